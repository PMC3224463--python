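"""Expression breadth and tissue specificity of gene expression.

Covers probe-to-gene assignment, expressed-gene calling (intensity cutoff or
present-call policy), seeded tissue resampling, the non-constitutive to
constitutive gene-count ratio, the tau (τ) tissue-specificity statistic, and
rank-based distribution comparisons between replicate summaries.

τ for one gene over N tissues with nonnegative expression values x is

    τ = Σ_i (1 − x_i / max(x)) / (N − 1)

so τ = 0 for perfectly uniform expression and τ = 1 for single-tissue
expression.  Negative inputs are clipped to 0; an all-zero gene has no τ and
is excluded from averaging.

A gene is *constitutive* for a sampled tissue subset when it is called
expressed in every sampled tissue; genes expressed in none of the sampled
tissues are excluded before counting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "CallPolicy",
    "ResamplingConfig",
    "ReplicateSummary",
    "assign_probes",
    "call_expressed",
    "sample_tissues",
    "constitutive_ratio",
    "tau",
    "tau_matrix",
    "replicate_summaries",
    "compare_distributions",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionMatrix:
    """Genes × tissues expression data.

    mode='intensity': ``values`` is a (genes, tissues) float array.
    mode='calls': ``calls`` is a (genes, tissues, replicates) boolean array
    of per-replicate present/absent calls.
    """

    gene_ids: list[str]
    tissue_labels: list[str]
    mode: str
    values: np.ndarray | None = None
    calls: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.tissue_labels)) != len(self.tissue_labels):
            raise ValueError("duplicate tissue labels")
        shape = (len(self.gene_ids), len(self.tissue_labels))
        if self.mode == "intensity":
            if self.values is None or self.values.shape != shape:
                raise ValueError(f"intensity mode needs values of shape {shape}")
        elif self.mode == "calls":
            if self.calls is None or self.calls.shape[:2] != shape:
                raise ValueError(f"calls mode needs calls of shape {shape} + (reps,)")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_replicates(self) -> int:
        if self.mode != "calls":
            raise ValueError("replicates only defined in calls mode")
        return self.calls.shape[2]

    def intensity_like(self) -> np.ndarray:
        """A (genes, tissues) float view usable for τ: raw intensities, or the
        per-tissue present-call fraction in calls mode."""
        if self.mode == "intensity":
            return self.values
        return self.calls.mean(axis=2)


@dataclass(frozen=True)
class CallPolicy:
    """Expressed-gene calling rule, matched to the matrix mode.

    intensity: expressed iff value strictly greater than ``cutoff``.
    calls: expressed iff at least ``min_calls`` present calls per tissue.
    """

    mode: str = "intensity"
    cutoff: float = 200.0
    min_calls: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("intensity", "calls"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if self.cutoff <= 0 or self.min_calls <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class ResamplingConfig:
    k_tissues: int = 10
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_tissues < 1 or self.n_reps < 1:
            raise ValueError("k_tissues and n_reps must be positive")


@dataclass(frozen=True)
class ReplicateSummary:
    """The three per-replicate measurements over the analyzed genes."""

    n_constitutive: int
    n_nonconstitutive: int
    log2_ratio: float  # NaN when no constitutive genes (undefined)
    mean_tau: float
    median_utr_bp: float


def assign_probes(
    probes: Sequence[tuple[str, str]],
    cdnas: Sequence[tuple[str, str]],
    expr: pd.DataFrame,
) -> dict[str, str]:
    """Map genes to microarray probes by exact sequence match.

    A probe maps to a gene iff its sequence occurs verbatim in the gene's
    cDNA.  Probes hitting two or more genes are discarded; when several
    probes remain for one gene, the one with the highest total expression
    across tissues (rows of ``expr``, indexed by probe id) wins, ties broken
    by lexicographic probe id.
    """
    probe_hits: dict[str, list[str]] = {}
    for probe_id, probe_seq in probes:
        pseq = probe_seq.upper().replace("U", "T")
        hits = [g for g, cseq in cdnas if pseq in cseq.upper().replace("U", "T")]
        if hits:
            probe_hits[probe_id] = hits
    row_sums = expr.sum(axis=1)
    per_gene: dict[str, list[str]] = {}
    for probe_id, hits in probe_hits.items():
        if len(set(hits)) != 1:
            continue  # multi-gene probes excluded
        per_gene.setdefault(hits[0], []).append(probe_id)
    out: dict[str, str] = {}
    for gene, pids in per_gene.items():
        out[gene] = min(
            pids, key=lambda p: (-float(row_sums.get(p, 0.0)), p)
        )
    return out


def call_expressed(matrix: ExpressionMatrix, policy: CallPolicy) -> np.ndarray:
    """Genes × tissues boolean grid of expressed calls."""
    if matrix.mode != policy.mode:
        raise ValueError(
            f"policy mode {policy.mode!r} does not match matrix mode {matrix.mode!r}"
        )
    if matrix.mode == "intensity":
        return matrix.values > policy.cutoff
    if policy.min_calls > matrix.n_replicates:
        raise ValueError("min_calls exceeds replicate count")
    return matrix.calls.sum(axis=2) >= policy.min_calls


def sample_tissues(
    tissue_labels: Sequence[str], cfg: ResamplingConfig
) -> list[tuple[str, ...]]:
    """n_reps subsets of k distinct tissues, uniform without replacement."""
    n = len(tissue_labels)
    if cfg.k_tissues > n:
        raise ValueError(f"k_tissues={cfg.k_tissues} exceeds {n} available tissues")
    rng = np.random.default_rng(cfg.seed)
    labels = np.asarray(tissue_labels, dtype=object)
    return [
        tuple(labels[rng.choice(n, size=cfg.k_tissues, replace=False)])
        for _ in range(cfg.n_reps)
    ]


def constitutive_ratio(expressed: np.ndarray) -> tuple[int, int, float]:
    """Counts and log2 ratio of non-constitutive to constitutive genes.

    ``expressed`` is a genes × sampled-tissues boolean grid.  Genes expressed
    in no sampled tissue are excluded; constitutive = expressed in every
    sampled tissue.  Returns (n_constitutive, n_nonconstitutive, log2_ratio);
    the ratio is NaN when there is no constitutive gene (undefined) and -inf
    when there is no non-constitutive gene.
    """
    expressed = np.asarray(expressed, dtype=bool)
    if expressed.ndim != 2 or expressed.shape[1] == 0:
        raise ValueError("expressed grid must be genes x tissues with >=1 tissue")
    n_per_gene = expressed.sum(axis=1)
    analyzed = n_per_gene > 0
    n_con = int((n_per_gene == expressed.shape[1]).sum())
    n_noncon = int(analyzed.sum()) - n_con
    if n_con == 0:
        ratio = math.nan
    elif n_noncon == 0:
        ratio = -math.inf
    else:
        ratio = math.log2(n_noncon / n_con)
    return n_con, n_noncon, ratio


def tau(values: Sequence[float]) -> float:
    """Tissue-specificity τ of one gene; NaN if max(values) ≤ 0."""
    x = np.clip(np.asarray(values, dtype=float), 0.0, None)
    if x.size < 2:
        raise ValueError("τ needs at least 2 tissues")
    m = x.max()
    if m <= 0:
        return math.nan
    return float((1.0 - x / m).sum() / (x.size - 1))


def tau_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise τ over a genes × tissues grid; NaN rows where max ≤ 0."""
    x = np.clip(np.asarray(values, dtype=float), 0.0, None)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a genes x tissues grid with >=2 tissues")
    m = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (1.0 - x / m[:, None]).sum(axis=1) / (x.shape[1] - 1)
    t[m <= 0] = math.nan
    return t


def replicate_summaries(
    matrix: ExpressionMatrix,
    policy: CallPolicy,
    cfg: ResamplingConfig,
    utr_lengths: Mapping[str, float],
) -> list[ReplicateSummary]:
    """The three measurements per tissue-resampling replicate.

    Per replicate: restrict to the sampled tissues, drop genes expressed in
    none of them, then measure (a) the median 5'UTR length of analyzed genes
    present in ``utr_lengths``, (b) log2 non-constitutive:constitutive, and
    (c) mean τ computed from the sampled-tissue values only.
    """
    genes = matrix.gene_ids
    length_vec = np.array(
        [utr_lengths.get(g, math.nan) for g in genes], dtype=float
    )
    if np.isnan(length_vec).all():
        raise ValueError("no overlap between matrix genes and utr_lengths")
    expressed = call_expressed(matrix, policy)
    intensity = matrix.intensity_like()
    label_idx = {t: i for i, t in enumerate(matrix.tissue_labels)}
    out = []
    for subset in sample_tissues(matrix.tissue_labels, cfg):
        idx = np.array([label_idx[t] for t in subset])
        ex = expressed[:, idx]
        n_per_gene = ex.sum(axis=1)
        analyzed = n_per_gene > 0
        n_con, n_noncon, log2_ratio = constitutive_ratio(ex[analyzed])
        taus = tau_matrix(intensity[analyzed][:, idx])
        mean_tau = float(np.nanmean(taus)) if np.isfinite(taus).any() else math.nan
        lens = length_vec[analyzed]
        lens = lens[~np.isnan(lens)]
        med_len = float(np.median(lens)) if lens.size else math.nan
        out.append(
            ReplicateSummary(
                n_constitutive=n_con,
                n_nonconstitutive=n_noncon,
                log2_ratio=log2_ratio,
                mean_tau=mean_tau,
                median_utr_bp=med_len,
            )
        )
    return out


def _exact_enumeration(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exhaustive two-sided rank-sum test over all C(n+m, n) group splits."""
    pooled = np.concatenate([a, b])
    n, total = len(a), len(pooled)
    ranks = stats.rankdata(pooled)  # midranks
    mn = n * (total - n)
    r_obs = ranks[:n].sum()
    u_obs = r_obs - n * (n + 1) / 2
    dev_obs = abs(u_obs - mn / 2)
    count = 0
    n_splits = 0
    for combo in itertools.combinations(range(total), n):
        r = ranks[list(combo)].sum()
        u = r - n * (n + 1) / 2
        if abs(u - mn / 2) >= dev_obs - 1e-12:
            count += 1
        n_splits += 1
    return float(u_obs), count / n_splits


def compare_distributions(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (a vs b) with a two-sided p.

    Exact enumeration when both samples have at most 8 values (scipy's exact
    distribution without ties, in-package exhaustive split enumeration with
    ties); otherwise the normal approximation with midrank ties, tie-corrected
    variance, and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    small = a.size <= 8 and b.size <= 8
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if small and has_ties:
        return _exact_enumeration(a, b)
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# TSV dialects: first line "#mode=intensity" or "#mode=calls replicates=R".
# Intensity: genes x tissues floats.  Calls: one column per tissue/replicate
# named "<tissue>|rep<i>", values 0/1.


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    if matrix.mode == "intensity":
        df = pd.DataFrame(
            matrix.values, index=matrix.gene_ids, columns=matrix.tissue_labels
        )
        header = "#mode=intensity\n"
    else:
        reps = matrix.n_replicates
        cols = [
            f"{t}|rep{i}" for t in matrix.tissue_labels for i in range(reps)
        ]
        flat = matrix.calls.reshape(len(matrix.gene_ids), -1).astype(int)
        df = pd.DataFrame(flat, index=matrix.gene_ids, columns=cols)
        header = f"#mode=calls replicates={reps}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t", index_col="gene_id")
    if not header.startswith("#mode="):
        raise ValueError(f"{path}: missing '#mode=' dialect header")
    if header == "#mode=intensity":
        return ExpressionMatrix(
            gene_ids=[str(g) for g in df.index],
            tissue_labels=[str(c) for c in df.columns],
            mode="intensity",
            values=df.to_numpy(dtype=float),
        )
    reps = int(header.split("replicates=")[1])
    tissues: list[str] = []
    for c in df.columns:
        t = c.rsplit("|rep", 1)[0]
        if t not in tissues:
            tissues.append(t)
    calls = df.to_numpy(dtype=int).reshape(len(df), len(tissues), reps).astype(bool)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        tissue_labels=tissues,
        mode="calls",
        calls=calls,
    )
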
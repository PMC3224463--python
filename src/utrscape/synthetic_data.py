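"""Synthetic multi-species panels with planted ground truth.

Generates everything the analysis consumes — a species tree, per-species
transcript annotations with 5'UTR sequences, expression matrices, and a
species trait table — while emitting the planted truth (purity labels, true
τ per gene, Brownian trait values) to a side channel the analysis never
reads.  This makes every downstream stage testable without any external
database.

What is emulated:
  * a pure-birth (Yule, unit rate) species tree with positive branch lengths;
  * two traits evolving jointly by correlated Brownian motion on that tree —
    the per-species log-median 5'UTR length and a log cell-type-count-like
    complexity trait — with a planted correlation;
  * multi-isoform genes with mixed annotation statuses, with/without protein
    product and annotated 5'UTR, and a controlled fraction of 5'UTRs planted
    to overlap another isoform's CDS (non-"pure");
  * lognormal 5'UTR lengths whose species log-mean is the Brownian trait;
  * expression matrices with a controllable constitutive fraction and a
    tissue-specificity knob: non-constitutive genes draw tissue weights from
    a symmetric Dirichlet with concentration 1/(1 + specificity_strength),
    so larger strength concentrates expression into fewer tissues.

Gene loci are laid out on disjoint genomic lanes so that planted purity
labels are exact by construction: a transcript is non-pure iff an extra CDS
interval was injected into a sibling isoform inside its 5'UTR.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression_profiles import ExpressionMatrix, tau_matrix, write_expression_tsv
from .utr_catalog import TranscriptRecord, write_annotation_table

__all__ = [
    "PanelConfig",
    "Panel",
    "gen_tree",
    "gen_bm_traits",
    "gen_annotations",
    "gen_expression",
    "gen_panel",
    "write_panel",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PanelConfig:
    """Knobs of the synthetic study panel.  Same seed ⇒ identical outputs."""

    n_species: int = 15
    n_genes: int = 300
    n_tissues: int = 12
    utr_length_log_mean: float = 4.8  # log-bp; exp(4.8) ≈ 122 bp median
    utr_length_log_sd: float = 0.9
    frac_constitutive: float = 0.3
    specificity_strength: float = 2.0
    trait_correlation: float = 0.0
    seed: int = 0
    # annotation composition
    frac_known: float = 0.85
    frac_protein: float = 0.9
    frac_with_utr: float = 0.9
    frac_nonpure: float = 0.3  # among multi-isoform, UTR-bearing transcripts
    frac_excluded: float = 0.0  # homology-purge stand-in flag
    gc_content: float = 0.45
    # expression
    expression_noise_sd: float = 0.1
    call_replicates: int = 4
    expression_mode: str = "intensity"
    # Brownian motion scales (per unit branch length, log scale)
    bm_sigma_utr: float = 0.4
    bm_sigma_complexity: float = 0.4

    def __post_init__(self) -> None:
        for name in ("n_species", "n_genes", "n_tissues", "call_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for name in (
            "frac_constitutive",
            "frac_known",
            "frac_protein",
            "frac_with_utr",
            "frac_nonpure",
            "frac_excluded",
            "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.trait_correlation) > 1:
            raise ValueError("|trait_correlation| must be <= 1")
        if self.specificity_strength < 0:
            raise ValueError("specificity_strength must be nonnegative")
        if self.utr_length_log_sd <= 0:
            raise ValueError("utr_length_log_sd must be positive")
        if self.bm_sigma_utr <= 0 or self.bm_sigma_complexity <= 0:
            raise ValueError("BM sigmas must be positive")
        if self.expression_mode not in ("intensity", "calls"):
            raise ValueError(f"unknown expression_mode {self.expression_mode!r}")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "PanelConfig":
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


# ---------------------------------------------------------------------------
# Tree and trait generation


class _YuleNode:
    __slots__ = ("children", "length", "label")

    def __init__(self) -> None:
        self.children: list[_YuleNode] = []
        self.length = 0.0
        self.label: str | None = None


def gen_tree(n_species: int, seed: int) -> str:
    """Pure-birth (Yule, unit rate) tree as Newick with positive lengths."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = _rng(seed, "tree")
    root = _YuleNode()
    left, right = _YuleNode(), _YuleNode()
    root.children = [left, right]
    active = [left, right]
    while len(active) < n_species:
        k = len(active)
        dt = rng.exponential(1.0 / k)
        for node in active:
            node.length += dt
        idx = int(rng.integers(k))
        parent = active[idx]
        c1, c2 = _YuleNode(), _YuleNode()
        parent.children = [c1, c2]
        active[idx : idx + 1] = [c1, c2]
    # final hold so the youngest pendant branches are strictly positive
    dt = rng.exponential(1.0 / n_species)
    for node in active:
        node.length += dt
    # label tips in preorder for a stable Newick string
    counter = [0]

    def label(node: _YuleNode) -> None:
        if not node.children:
            counter[0] += 1
            node.label = f"sp{counter[0]:02d}"
        for c in node.children:
            label(c)

    label(root)

    def newick(node: _YuleNode) -> str:
        if not node.children:
            return f"{node.label}:{node.length:.10g}"
        inner = ",".join(newick(c) for c in node.children)
        if node is root:
            return f"({inner})"
        return f"({inner}):{node.length:.10g}"

    return newick(root) + ";"


def gen_bm_traits(
    tree: str | dendropy.Tree,
    rho: float,
    sigma1: float,
    sigma2: float,
    seed: int,
    x0: float = 0.0,
    y0: float = 0.0,
) -> pd.DataFrame:
    """Two traits under correlated Brownian motion; one row per tip.

    Increments on a branch of length t are bivariate normal with variances
    sigma_i^2 * t and correlation rho.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigmas must be positive")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", rooting="force-rooted")
    rng = _rng(seed, "bm-traits")
    # Cholesky-style factor valid also at |rho| = 1
    chol = np.array(
        [[sigma1, 0.0], [rho * sigma2, sigma2 * math.sqrt(max(0.0, 1.0 - rho * rho))]]
    )
    state: dict[int, np.ndarray] = {id(tree.seed_node): np.array([x0, y0])}
    rows = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            val = state[id(node)]
        else:
            t = node.edge.length or 0.0
            z = rng.standard_normal(2)
            val = state[id(node.parent_node)] + math.sqrt(t) * (chol @ z)
            state[id(node)] = val
        if node.is_leaf():
            rows[node.taxon.label] = val
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["trait1", "trait2"]
    ).rename_axis("species")


# ---------------------------------------------------------------------------
# Annotations and sequences

_GENE_SPACING = 100_000
_LANE_WIDTH = 20_000
_ANCHOR = 5_000  # CDS start offset within a lane
_CDS_LEN = 900
_MAX_UTR = 4_800


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASE_BYTES[rng.choice(4, size=length, p=p)].tobytes().decode()


def gen_annotations(
    config: PanelConfig, species: str, log_mean: float | None = None
) -> tuple[list[TranscriptRecord], dict[str, str], pd.DataFrame]:
    """One species' annotation table, 5'UTR sequences, and planted truth.

    Returns (records, {transcript_id: utr5_seq}, truth table).  The truth
    table carries eligibility and exact purity labels for every transcript.
    """
    rng = _rng(config.seed, f"annot:{species}")
    mu = config.utr_length_log_mean if log_mean is None else log_mean
    records: list[TranscriptRecord] = []
    seqs: dict[str, str] = {}
    truth_rows = []
    extra_cds: dict[str, list[tuple[int, int]]] = {}
    gene_meta = []
    for i in range(config.n_genes):
        gene_id = f"{species}_g{i:05d}"
        n_iso = int(rng.choice([1, 2, 3, 4], p=[0.45, 0.30, 0.15, 0.10]))
        strand = "+" if rng.random() < 0.5 else "-"
        offset = i * _GENE_SPACING
        iso_meta = []
        for j in range(n_iso):
            tid = f"{gene_id}_t{j}"
            status = (
                "known"
                if rng.random() < config.frac_known
                else ("novel" if rng.random() < 0.5 else "predicted")
            )
            protein = rng.random() < config.frac_protein
            has_utr = rng.random() < config.frac_with_utr
            length = int(
                np.clip(
                    round(math.exp(rng.normal(mu, config.utr_length_log_sd))),
                    10,
                    _MAX_UTR,
                )
            )
            base = offset + j * _LANE_WIDTH
            anchor = base + _ANCHOR
            if strand == "+":
                utr = (anchor - length, anchor)
                cds = (anchor, anchor + _CDS_LEN)
            else:
                utr = (anchor, anchor + length)
                cds = (anchor - _CDS_LEN, anchor)
            nonpure = (
                has_utr and n_iso >= 2 and rng.random() < config.frac_nonpure
            )
            excluded = has_utr and rng.random() < config.frac_excluded
            iso_meta.append(
                dict(
                    tid=tid,
                    status=status,
                    protein=protein,
                    has_utr=has_utr,
                    length=length,
                    utr=utr,
                    cds=cds,
                    nonpure=nonpure,
                    excluded=excluded,
                )
            )
        # plant non-purity: inject a CDS fragment of a sibling inside the UTR
        for j, m in enumerate(iso_meta):
            if not m["nonpure"]:
                continue
            sib = iso_meta[(j + 1) % n_iso]["tid"]
            u0, u1 = m["utr"]
            w = u1 - u0
            frag = (u0 + w // 3, min(u1, u0 + w // 3 + max(1, w // 4)))
            extra_cds.setdefault(sib, []).append(frag)
        gene_meta.append((gene_id, strand, iso_meta))
    # one pooled draw for all sequences (much faster than per-transcript)
    total_len = sum(
        m["length"] for _, _, iso in gene_meta for m in iso if m["has_utr"]
    )
    pool = _random_seq(rng, total_len, config.gc_content)
    cursor = 0
    for gene_id, strand, iso_meta in gene_meta:
        for m in iso_meta:
            if m["has_utr"]:
                seq = pool[cursor : cursor + m["length"]]
                cursor += m["length"]
            else:
                seq = None
            cds_ivs = [m["cds"], *extra_cds.get(m["tid"], [])]
            rec = TranscriptRecord(
                gene_id=gene_id,
                transcript_id=m["tid"],
                status=m["status"],
                has_protein_product=m["protein"],
                chrom="chr1",
                strand=strand,
                utr5_intervals=(m["utr"],) if m["has_utr"] else (),
                cds_intervals=tuple(cds_ivs),
                utr5_seq=seq,
                excluded=m["excluded"],
            )
            records.append(rec)
            if seq is not None:
                seqs[m["tid"]] = seq
            truth_rows.append(
                {
                    "transcript_id": m["tid"],
                    "gene_id": gene_id,
                    "has_utr": m["has_utr"],
                    "status": m["status"],
                    "protein_product": m["protein"],
                    "eligible": m["has_utr"]
                    and m["status"] == "known"
                    and m["protein"],
                    "planted_pure": (not m["nonpure"]) if m["has_utr"] else None,
                    "utr_length": m["length"] if m["has_utr"] else None,
                    "excluded": m["excluded"],
                }
            )
    return records, seqs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Expression


def gen_expression(
    config: PanelConfig, species: str, mode: str | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """One species' expression matrix plus ground truth (true τ, flags).

    Constitutive genes get near-uniform means well above the intensity
    cutoff in every tissue; the rest distribute a total expression budget
    over tissues by a symmetric Dirichlet whose concentration shrinks as
    ``specificity_strength`` grows.  True τ is computed from the noiseless
    means.  Intensity mode multiplies means by lognormal noise; calls mode
    draws per-replicate present calls with probability following a Hill
    curve of the mean centred at the cutoff.
    """
    mode = mode or config.expression_mode
    if mode not in ("intensity", "calls"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = _rng(config.seed, f"expr:{species}")
    g, t = config.n_genes, config.n_tissues
    gene_ids = [f"{species}_g{i:05d}" for i in range(g)]
    tissues = [f"t{j:02d}" for j in range(t)]
    constitutive = rng.random(g) < config.frac_constitutive
    means = np.empty((g, t))
    scale = 10.0 ** rng.uniform(2.7, 3.7, size=g)  # ~500..5000
    n_con = int(constitutive.sum())
    means[constitutive] = scale[constitutive, None] * rng.uniform(
        0.8, 1.2, size=(n_con, t)
    )
    alpha = 1.0 / (1.0 + config.specificity_strength)
    n_var = g - n_con
    if n_var:
        weights = rng.dirichlet(np.full(t, alpha), size=n_var)
        means[~constitutive] = scale[~constitutive, None] * t * weights
    true_tau = tau_matrix(means)
    if mode == "intensity":
        noise = np.exp(config.expression_noise_sd * rng.standard_normal((g, t)))
        matrix = ExpressionMatrix(
            gene_ids=gene_ids,
            tissue_labels=tissues,
            mode="intensity",
            values=means * noise,
        )
    else:
        p = means**3 / (means**3 + 200.0**3)
        calls = rng.random((g, t, config.call_replicates)) < p[:, :, None]
        matrix = ExpressionMatrix(
            gene_ids=gene_ids, tissue_labels=tissues, mode="calls", calls=calls
        )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "constitutive": constitutive,
            "true_tau": true_tau,
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Whole panels


@dataclass
class Panel:
    config: PanelConfig
    tree_newick: str
    species: list[str]
    traits: pd.DataFrame  # planted BM tip values (truth side channel)
    cell_types: pd.Series  # analysis input: complexity trait per species
    annotations: dict[str, list[TranscriptRecord]]
    sequences: dict[str, dict[str, str]]
    annotation_truth: dict[str, pd.DataFrame]
    expression: dict[str, ExpressionMatrix]
    expression_truth: dict[str, pd.DataFrame]


def gen_panel(config: PanelConfig) -> Panel:
    """Full panel: tree, BM traits, per-species annotations and expression.

    The species log-median UTR length is the first Brownian trait (root at
    ``utr_length_log_mean``); the cell-type-like complexity input is the
    exponential of the second trait (root at log 150, a mammal-scale count).
    """
    newick = gen_tree(config.n_species, config.seed)
    traits = gen_bm_traits(
        newick,
        rho=config.trait_correlation,
        sigma1=config.bm_sigma_utr,
        sigma2=config.bm_sigma_complexity,
        seed=config.seed,
        x0=config.utr_length_log_mean,
        y0=math.log(150.0),
    )
    species = sorted(traits.index)
    cell_types = np.exp(traits["trait2"]).round(2).rename("cell_types")
    annotations, sequences, ann_truth = {}, {}, {}
    expression, expr_truth = {}, {}
    for sp in species:
        recs, seqs, truth = gen_annotations(
            config, sp, log_mean=float(traits.loc[sp, "trait1"])
        )
        annotations[sp] = recs
        sequences[sp] = seqs
        ann_truth[sp] = truth
        mat, etruth = gen_expression(config, sp)
        expression[sp] = mat
        expr_truth[sp] = etruth
    return Panel(
        config=config,
        tree_newick=newick,
        species=species,
        traits=traits,
        cell_types=cell_types,
        annotations=annotations,
        sequences=sequences,
        annotation_truth=ann_truth,
        expression=expression,
        expression_truth=expr_truth,
    )


def write_panel(panel: Panel, outdir: str | Path) -> None:
    """Write analysis inputs under ``outdir`` and planted truth under
    ``outdir/truth`` (the analysis modules never read the latter)."""
    outdir = Path(outdir)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(panel.tree_newick + "\n")
    pd.DataFrame({"species": panel.species}).assign(
        cell_types=[panel.cell_types[sp] for sp in panel.species]
    ).to_csv(outdir / "traits.tsv", sep="\t", index=False)
    panel.traits.to_csv(truth_dir / "bm_traits.tsv", sep="\t")
    for sp in panel.species:
        spdir = outdir / sp
        spdir.mkdir(exist_ok=True)
        write_annotation_table(panel.annotations[sp], spdir / "annotations.tsv")
        seq_records = [
            SeqRecord(Seq(seq), id=tid, description="")
            for tid, seq in panel.sequences[sp].items()
        ]
        SeqIO.write(seq_records, spdir / "utr5.fasta", "fasta")
        write_expression_tsv(panel.expression[sp], spdir / "expression.tsv")
        panel.annotation_truth[sp].to_csv(
            truth_dir / f"{sp}_annotations.tsv", sep="\t", index=False
        )
        panel.expression_truth[sp].to_csv(
            truth_dir / f"{sp}_expression.tsv", sep="\t", index=False
        )
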
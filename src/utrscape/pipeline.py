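"""End-to-end orchestration: catalog → scanner → expression → contrasts.

A single seeded run produces, per species, the 5'UTR length summary and
uAUG/uORF rates, the tissue-resampling replicate summaries, and the
contrast correlations between species traits.  Outputs are labelled by the
five hypothesized connections between 5'UTR elongation and organismal
complexity:

  (i)   5'UTR length vs expression breadth/specificity (replicate median
        length distributions compared between species),
  (ii)  breadth/specificity ordering across species (replicate τ and
        log2 non-constitutive:constitutive ratio distributions),
  (iii) uAUG/uORF counts vs 5'UTR length (contrast correlation),
  (iv)  uAUG/uORF counts vs cell-type count (contrast correlation),
  (v)   5'UTR length vs cell-type count (contrast correlation).

Synthetic panels are written to disk and read back through the standard
readers, so the analysis only ever sees the same file formats a real-data
run would supply; planted truth stays in its side directory, unread.

One root seed deterministically derives per-stage seeds by hashing stage
names, so stages can be rerun stand-alone with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from . import expression_profiles as xp
from . import orf_scanner, phylo_contrasts, synthetic_data, utr_catalog

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("median_utr_bp", "cell_types"),
    ("uaug_per_gene", "cell_types"),
    ("uorf_per_gene", "cell_types"),
    ("uaug_per_gene", "median_utr_bp"),
    ("uorf_per_gene", "median_utr_bp"),
)

_CONNECTION_OF_PAIR = {
    ("median_utr_bp", "cell_types"): "v",
    ("mean_utr_bp", "cell_types"): "v",
    ("uaug_per_gene", "cell_types"): "iv",
    ("uorf_per_gene", "cell_types"): "iv",
    ("uaug_per_gene", "median_utr_bp"): "iii",
    ("uorf_per_gene", "median_utr_bp"): "iii",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class RunConfig:
    outdir: Path
    seed: int = 0
    panel: synthetic_data.PanelConfig | None = None  # synthesize inputs
    input_dir: Path | None = None  # or read an existing layout
    selection_mode: str = "random"
    cage_bed: Path | None = None
    cage_slack_bp: int = 0
    intensity_cutoff: float = 200.0
    min_calls: int = 3
    k_tissues: int = 10
    n_reps: int = 1000
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS

    def __post_init__(self) -> None:
        if (self.panel is None) == (self.input_dir is None):
            raise ValueError("exactly one of panel/input_dir must be given")
        if self.selection_mode not in ("random", "pure"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")


@dataclass
class RunReport:
    outdir: Path
    payload: dict
    files: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True)


def _stage_seed(root: int, stage: str) -> int:
    return (root ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(cfg: RunConfig) -> RunReport:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    # --- stage: inputs -----------------------------------------------------
    stage = "synth"
    try:
        if cfg.panel is not None:
            panel_cfg = dataclasses.replace(
                cfg.panel, seed=_stage_seed(cfg.seed, stage)
            )
            input_dir = outdir / "inputs"
            synthetic_data.write_panel(synthetic_data.gen_panel(panel_cfg), input_dir)
        else:
            input_dir = Path(cfg.input_dir)
        tree_text = (input_dir / "tree.nwk").read_text()
        tree = phylo_contrasts.parse_newick(tree_text)
        species_traits = pd.read_csv(
            input_dir / "traits.tsv", sep="\t", index_col="species"
        )
        species = sorted(
            d.name for d in input_dir.iterdir()
            if d.is_dir() and (d / "annotations.tsv").exists()
        )
        if not species:
            raise FileNotFoundError(f"no species directories under {input_dir}")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: catalog ----------------------------------------------------
    stage = "catalog"
    try:
        seed = _stage_seed(cfg.seed, stage)
        cage = (
            utr_catalog.read_cage_bed(cfg.cage_bed) if cfg.cage_bed else None
        )
        reps_by_species: dict[str, list[utr_catalog.TranscriptRecord]] = {}
        summaries = {}
        rep_rows = []
        for sp in species:
            records = utr_catalog.read_annotation_table(
                input_dir / sp / "annotations.tsv"
            )
            seqs = _read_fasta(input_dir / sp / "utr5.fasta")
            records = utr_catalog.attach_sequences(records, seqs)
            eligible = utr_catalog.filter_eligible(records)
            if cage is not None:
                eligible = utr_catalog.cage_filter(
                    eligible, cage, slack_bp=cfg.cage_slack_bp
                )
            reps = utr_catalog.select_representatives(
                eligible, mode=cfg.selection_mode, seed=seed
            )
            if not reps:
                raise ValueError(f"no representative transcripts for {sp}")
            reps_by_species[sp] = reps
            summaries[sp] = utr_catalog.summarize_lengths(reps, species=sp)
            rep_rows += [
                {
                    "species": sp,
                    "gene_id": r.gene_id,
                    "transcript_id": r.transcript_id,
                    "utr5_length": r.utr5_length,
                }
                for r in reps
            ]
        pd.DataFrame(rep_rows).to_csv(
            outdir / "representatives.tsv", sep="\t", index=False
        )
        files["representatives"] = "representatives.tsv"
        summary_df = pd.DataFrame(
            [dataclasses.asdict(s) for s in summaries.values()]
        )
        summary_df.to_csv(outdir / "length_summary.tsv", sep="\t", index=False)
        files["length_summary"] = "length_summary.tsv"
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: scan -------------------------------------------------------
    stage = "scan"
    try:
        rates = {}
        scan_rows = []
        for sp in species:
            reports = orf_scanner.scan_sequences(
                (r.transcript_id, r.utr5_seq)
                for r in reps_by_species[sp]
                if r.utr5_seq is not None
            )
            if not reports:
                raise ValueError(f"no 5'UTR sequences to scan for {sp}")
            uaug, uorf = orf_scanner.per_gene_element_rates(reports)
            rates[sp] = {"uaug_per_gene": uaug, "uorf_per_gene": uorf}
            scan_rows += [
                {
                    "species": sp,
                    "transcript_id": r.transcript_id,
                    "n_uaug": r.n_uaug,
                    "n_uorf": r.n_uorf,
                }
                for r in reports
            ]
        pd.DataFrame(scan_rows).to_csv(outdir / "scan.tsv", sep="\t", index=False)
        files["scan"] = "scan.tsv"
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: express ----------------------------------------------------
    stage = "express"
    try:
        seed = _stage_seed(cfg.seed, stage)
        replicate_files = {}
        per_species_summaries: dict[str, pd.DataFrame] = {}
        for sp in species:
            matrix = xp.read_expression_tsv(input_dir / sp / "expression.tsv")
            policy = xp.CallPolicy(
                mode=matrix.mode,
                cutoff=cfg.intensity_cutoff,
                min_calls=cfg.min_calls,
            )
            lengths = {
                r.gene_id: float(r.utr5_length) for r in reps_by_species[sp]
            }
            rcfg = xp.ResamplingConfig(
                k_tissues=min(cfg.k_tissues, len(matrix.tissue_labels)),
                n_reps=cfg.n_reps,
                seed=seed,
            )
            sums = xp.replicate_summaries(matrix, policy, rcfg, lengths)
            df = pd.DataFrame([dataclasses.asdict(s) for s in sums])
            name = f"replicates_{sp}.tsv"
            df.to_csv(outdir / name, sep="\t", index=False)
            replicate_files[sp] = name
            per_species_summaries[sp] = df
        files["replicates"] = json.dumps(replicate_files, sort_keys=True)
        # cross-species distribution tests (connections i and ii)
        test_rows = []
        for measure, connection in (
            ("median_utr_bp", "i"),
            ("mean_tau", "ii"),
            ("log2_ratio", "ii"),
        ):
            for a in species:
                for b in species:
                    if a >= b:
                        continue
                    xa = per_species_summaries[a][measure].dropna()
                    xb = per_species_summaries[b][measure].dropna()
                    if xa.empty or xb.empty:
                        continue
                    u, p = xp.compare_distributions(xa, xb)
                    test_rows.append(
                        {
                            "connection": connection,
                            "measure": measure,
                            "species_a": a,
                            "species_b": b,
                            "median_a": float(xa.median()),
                            "median_b": float(xb.median()),
                            "U": u,
                            "p_value": p,
                        }
                    )
        tests_df = pd.DataFrame(test_rows)
        tests_df.to_csv(outdir / "distribution_tests.tsv", sep="\t", index=False)
        files["distribution_tests"] = "distribution_tests.tsv"
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: contrast ---------------------------------------------------
    stage = "contrast"
    try:
        trait_table = pd.DataFrame(
            {
                "median_utr_bp": {sp: summaries[sp].median_bp for sp in species},
                "mean_utr_bp": {sp: summaries[sp].mean_bp for sp in species},
                "uaug_per_gene": {sp: rates[sp]["uaug_per_gene"] for sp in species},
                "uorf_per_gene": {sp: rates[sp]["uorf_per_gene"] for sp in species},
                "cell_types": species_traits["cell_types"],
            }
        ).rename_axis("species")
        trait_table.to_csv(outdir / "species_traits.tsv", sep="\t")
        files["species_traits"] = "species_traits.tsv"
        corr = phylo_contrasts.run_trait_correlations(
            tree, trait_table, pairs=list(cfg.pairs)
        )
        corr["connection"] = [
            _CONNECTION_OF_PAIR.get((x, y), "other")
            for x, y in zip(corr["trait_x"], corr["trait_y"])
        ]
        corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        files["correlations"] = "correlations.tsv"
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- report ------------------------------------------------------------
    connections: dict[str, list] = {"i": [], "ii": [], "iii": [], "iv": [], "v": []}
    for row in tests_df.to_dict(orient="records"):
        connections[row["connection"]].append(row)
    for row in corr.to_dict(orient="records"):
        conn = row.pop("connection")
        connections.setdefault(conn, []).append(row)
    payload = {
        "provenance": {
            "seed": cfg.seed,
            "selection_mode": cfg.selection_mode,
            "k_tissues": cfg.k_tissues,
            "n_reps": cfg.n_reps,
            "panel": (
                dataclasses.asdict(cfg.panel) if cfg.panel is not None else None
            ),
            "input_dir": str(cfg.input_dir) if cfg.input_dir else None,
        },
        "length_summaries": {
            sp: dataclasses.asdict(summaries[sp]) for sp in species
        },
        "element_rates": rates,
        "connections": connections,
        "files": files,
    }
    report = RunReport(outdir=outdir, payload=payload, files=files)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    logger.info("pipeline complete: %s", outdir / "report.json")
    return report
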
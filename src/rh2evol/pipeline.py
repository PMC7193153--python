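"""End-to-end runs: reconstruction, shift census, lineage rates.

Each run validates its configuration up front, executes the stage
pipeline, writes tab-separated reports plus a machine-readable JSON
manifest (config echo, seed, package version, input checksums) to the
output directory, and removes partial outputs if a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ancestral_inference import (
    export_map_fasta,
    export_reconstruction_tsv,
    marginal_reconstruction,
)
from .lineage_rates import LineageRate, compare_rates, rate_se, sequential_average_depth
from .phylo_core import optimize_branch_lengths, read_fasta, read_newick
from .spectral_tuning import (
    EXPLAINED_TOLERANCE_NM,
    LARGE_SHIFT_NM,
    SIGNIFICANCE_NM,
    branch_shifts,
    classify_explained,
    count_shifts,
    fraction_explained,
    shift_report_frame,
)
from .substitution_models import build_rate_matrix, get_model
from .synthetic_data import fixture_fig1, fixture_table1, read_annotated_tree

logger = logging.getLogger("rh2evol")

__all__ = ["RunConfig", "run_reconstruct", "run_shifts", "run_rates"]


@dataclass
class RunConfig:
    """Declarative run configuration; flags > file > defaults."""

    model: str = "JTT"
    alignment_path: str | None = None
    tree_path: str | None = None
    annotation_path: str | None = None
    assay_path: str | None = None
    reference_name: str | None = None
    site_window: tuple[int, int] = (31, 311)
    significance_nm: float = SIGNIFICANCE_NM
    large_nm: float = LARGE_SHIFT_NM
    explained_nm: float = EXPLAINED_TOLERANCE_NM
    pp_high: float = 0.95
    pp_mid: float = 0.70
    use_empirical_frequencies: bool = False
    divergence_times_years: dict[str, float] = field(default_factory=dict)
    lineage_focal_nodes: dict[str, str] = field(default_factory=dict)
    n_boot: int = 100
    seed: int = 0
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        for name in ("significance_nm", "large_nm", "explained_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.pp_mid < self.pp_high < 1):
            raise ValueError("PP thresholds must satisfy 0 < mid < high < 1")

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "site_window" in data:
            data["site_window"] = tuple(data["site_window"])
        return cls(**data)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, inputs: list[Path]) -> Path:
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
        "inputs": {str(p): _md5(p) for p in inputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


class _OutputSet:
    """Tracks written files so a failed stage leaves no partial outputs."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.written: list[Path] = []
        outdir.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.written.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def run_reconstruct(config: RunConfig) -> dict[str, Path]:
    """Branch-length optimization then marginal reconstruction, exported as
    TSV (posterior vectors) + FASTA (MAP sequences) + optimization log."""
    if not config.alignment_path or not Path(config.alignment_path).exists():
        raise FileNotFoundError(f"alignment not found: {config.alignment_path}")
    if not config.tree_path or not Path(config.tree_path).exists():
        raise FileNotFoundError(f"tree not found: {config.tree_path}")
    outdir = Path(config.output_dir)
    out = _OutputSet(outdir)
    stage = "read inputs"
    try:
        aln = read_fasta(config.alignment_path)
        aln.reference_name = config.reference_name
        aln.site_window = config.site_window if config.reference_name else None
        tree = read_newick(config.tree_path)
        model = get_model(config.model)
        freqs = None
        if config.use_empirical_frequencies:
            import numpy as np

            from .alphabet import AA_INDEX

            counts = np.zeros(20)
            for row in aln.rows:
                for ch in row:
                    if ch in AA_INDEX:
                        counts[AA_INDEX[ch]] += 1
            freqs = counts / counts.sum()
        Q = build_rate_matrix(model, frequencies_override=freqs)

        stage = "branch-length optimization"
        logger.info("optimizing branch lengths (%s)", config.model)
        result = optimize_branch_lengths(tree, aln, Q)
        opt_path = out.path("branch_lengths.tsv")
        pd.DataFrame(result.branch_table, columns=["branch", "initial", "final"]).to_csv(
            opt_path, sep="\t", index=False
        )

        stage = "marginal reconstruction"
        recon = marginal_reconstruction(
            result.tree, aln, Q, provenance=f"{config.model}/{aln.n_sequences}-seq"
        )
        tsv_path = out.path("reconstruction.tsv")
        export_reconstruction_tsv(recon, tsv_path)
        fasta_path = out.path("ancestral_map.fasta")
        export_map_fasta(recon, fasta_path)
        tree_path = out.path("optimized_tree.nwk")
        tree_path.write_text(result.tree.to_newick() + "\n")

        manifest = _write_manifest(
            outdir, config, [Path(config.alignment_path), Path(config.tree_path)]
        )
        return {
            "manifest": manifest,
            "branch_lengths": opt_path,
            "reconstruction": tsv_path,
            "ancestral_fasta": fasta_path,
            "optimized_tree": tree_path,
        }
    except Exception as exc:
        out.cleanup()
        raise RuntimeError(f"reconstruction run failed during {stage}: {exc}") from exc


def run_shifts(config: RunConfig) -> dict[str, object]:
    """Shift census + mutation-explanation report on an annotated tree and
    assay table (the packaged study fixtures by default)."""
    outdir = Path(config.output_dir)
    out = _OutputSet(outdir)
    stage = "load fixtures"
    try:
        if config.tree_path and config.annotation_path:
            fixture = read_annotated_tree(config.tree_path, config.annotation_path)
        else:
            fixture = fixture_fig1()
        if config.assay_path:
            from .spectral_tuning import MutationAssay, parse_mutation

            frame = pd.read_csv(config.assay_path, sep="\t")
            assays = [
                MutationAssay(
                    ancestral_id=r["ancestor"],
                    ancestral_lambda=float(r["ancestral_lambda"]),
                    mutations=tuple(parse_mutation(m) for m in r["mutations"].split("/")),
                    mutant_lambda=float(r["mutant_lambda"]),
                    descendant_id=r["descendant"],
                    descendant_lambda=float(r["descendant_lambda"]),
                )
                for _, r in frame.iterrows()
            ]
        else:
            assays = fixture_table1()

        stage = "shift census"
        records, skipped = branch_shifts(
            fixture.tree, significance=config.significance_nm, large=config.large_nm
        )
        n_sig, n_large, listing = count_shifts(
            records, significance=config.significance_nm, large=config.large_nm
        )
        shift_path = out.path("shifts.tsv")
        shift_report_frame(listing).to_csv(shift_path, sep="\t", index=False)

        stage = "explanation classification"
        if assays:
            table, n_single, n_multi = classify_explained(assays, tolerance=config.explained_nm)
            n_explained = n_single + n_multi
            fractions = []
            for a in assays:
                if a.complete and a.descendant_lambda != a.ancestral_lambda:
                    nm, pct = fraction_explained(
                        a.ancestral_lambda, a.mutant_lambda, a.descendant_lambda
                    )
                    fractions.append((a.ancestral_id, a.descendant_id, a.mutation_label, nm, pct))
            table.to_csv(out.path("explained.tsv"), sep="\t", index=False)
            pd.DataFrame(
                fractions,
                columns=["ancestor", "descendant", "mutations", "contribution_nm", "percent"],
            ).to_csv(out.path("fraction_explained.tsv"), sep="\t", index=False)
        else:
            logger.warning("empty assay table: explanation section skipped")
            table, n_explained = None, 0

        summary = {
            "n_significant": n_sig,
            "n_large": n_large,
            "n_explained": n_explained,
            "n_branches": len(records),
            "skipped_branches": skipped,
        }
        out.path("summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        inputs = [Path(p) for p in (config.tree_path, config.annotation_path, config.assay_path) if p]
        _write_manifest(outdir, config, inputs)
        return summary
    except Exception as exc:
        out.cleanup()
        raise RuntimeError(f"shift run failed during {stage}: {exc}") from exc


def run_rates(config: RunConfig) -> pd.DataFrame:
    """Lineage rates with bootstrap SEs and all pairwise Z comparisons."""
    if not config.lineage_focal_nodes:
        raise ValueError("no lineages configured (lineage_focal_nodes is empty)")
    missing = set(config.lineage_focal_nodes) - set(config.divergence_times_years)
    if missing:
        raise ValueError(f"origin time missing for lineage(s): {', '.join(sorted(missing))}")
    if not config.alignment_path or not Path(config.alignment_path).exists():
        raise FileNotFoundError(f"alignment not found: {config.alignment_path}")
    if not config.tree_path or not Path(config.tree_path).exists():
        raise FileNotFoundError(f"tree not found: {config.tree_path}")
    outdir = Path(config.output_dir)
    out = _OutputSet(outdir)
    stage = "read inputs"
    try:
        aln = read_fasta(config.alignment_path)
        tree = read_newick(config.tree_path)
        Q = build_rate_matrix(get_model(config.model))

        stage = "branch-length optimization"
        result = optimize_branch_lengths(tree, aln, Q)

        stage = "lineage rates"
        rates: dict[str, LineageRate] = {}
        rows = []
        for i, (lineage, focal) in enumerate(sorted(config.lineage_focal_nodes.items())):
            focal_tree_node = result.tree.node(focal)
            n_tips = sum(1 for n in result.tree.preorder() if n.is_leaf and _is_descendant(n, focal_tree_node))
            if n_tips < 2:
                raise ValueError(f"lineage {lineage!r} has fewer than 2 tips")
            t_origin = config.divergence_times_years[lineage]
            depth = sequential_average_depth(result.tree, focal)
            se, _ = rate_se(
                result.tree, focal, aln, Q, t_origin,
                n_boot=config.n_boot, seed=config.seed + i,
            )
            rates[lineage] = LineageRate(
                lineage_id=lineage, depth=depth, origin_time=t_origin,
                rate=depth / t_origin, se=se, n_boot=config.n_boot, seed=config.seed + i,
            )
            rows.append((lineage, depth, t_origin / 1e6, rates[lineage].rate, se, config.n_boot, config.seed + i))
        rate_frame = pd.DataFrame(
            rows, columns=["lineage", "depth", "origin_MYA", "rate_per_site_per_year", "se", "n_boot", "seed"]
        )
        rate_frame.to_csv(out.path("lineage_rates.tsv"), sep="\t", index=False)

        stage = "rate comparisons"
        comps = []
        ids = sorted(rates)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                z, p, sig5, sig1 = compare_rates(rates[a], rates[b])
                comps.append((a, b, z, p, sig5, sig1))
        comp_frame = pd.DataFrame(
            comps, columns=["lineage_1", "lineage_2", "Z", "p_value", "sig_5pct", "sig_1pct"]
        )
        comp_frame.to_csv(out.path("rate_comparisons.tsv"), sep="\t", index=False)
        _write_manifest(outdir, config, [Path(config.alignment_path), Path(config.tree_path)])
        return rate_frame
    except Exception as exc:
        out.cleanup()
        raise RuntimeError(f"rate run failed during {stage}: {exc}") from exc


def _is_descendant(node, ancestor) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False
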
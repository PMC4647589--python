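"""End-to-end orchestration: profiles -> matrix -> reconstruction -> reports.

Outputs are plain TSV/JSON and deterministic for fixed inputs, and every run
writes a manifest (input hashes, settings, package version) so a result can
be reproduced exactly from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .coding import (
    BinaryCharacterMatrix,
    FertilityCriterion,
    build_character_matrix,
    read_profiles_tsv,
)
from .mk import DEFAULT_Q_BOUNDS, CladeReport, clade_report
from .tree import CladeDefinition, parse_newick, set_unit_branch_lengths, write_newick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_asr", "summarize_origins", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics/exit codes."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Paths and settings for one reconstruction run."""

    tree_path: Path
    out_dir: Path
    matrix_path: Optional[Path] = None
    profiles_path: Optional[Path] = None
    clades_path: Optional[Path] = None
    threshold: float = 0.50
    criterion: FertilityCriterion = field(default_factory=FertilityCriterion)
    q_bounds: tuple[float, float] = DEFAULT_Q_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.matrix_path is None and self.profiles_path is None:
            raise ValueError("either a coded matrix or raw profiles are required")
        self.tree_path = Path(self.tree_path)
        self.out_dir = Path(self.out_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_clades(path: Optional[Path]) -> list[CladeDefinition]:
    if path is None:
        from .datasets import load_study_clades

        return load_study_clades()
    mapping = json.loads(Path(path).read_text())
    return [CladeDefinition(name, tips) for name, tips in mapping.items()]


def run_asr(config: RunConfig) -> CladeReport:
    """Run the reconstruction and write reports under ``config.out_dir``.

    Writes: ``clade_report.tsv`` (percent + likely flags), one
    ``asr_<class>.json`` ancestral-state table and one annotated Newick per
    character (node comments carry the percent 'present'), an
    ``origins.tsv`` summary, and ``manifest.json``.
    """
    try:
        tree = set_unit_branch_lengths(parse_newick(config.tree_path.read_text()))
    except Exception as exc:
        raise PipelineError("treeio", str(exc)) from exc

    try:
        if config.matrix_path is not None:
            matrix = BinaryCharacterMatrix.from_tsv(config.matrix_path)
        else:
            profiles = read_profiles_tsv(config.profiles_path)
            matrix = build_character_matrix(profiles, config.criterion)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("signal_coding", str(exc)) from exc

    clades = _load_clades(config.clades_path)
    try:
        report = clade_report(
            tree, matrix, clades,
            threshold=config.threshold, q_bounds=config.q_bounds,
        )
    except Exception as exc:
        raise PipelineError("mk_asr", str(exc)) from exc

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report.to_tsv(out / "clade_report.tsv")
    for char, res in report.per_character.items():
        slug = char.replace(" ", "_")
        table = res.marginal_proportions()
        (out / f"asr_{slug}.json").write_text(table.to_json(indent=1))
        (out / f"asr_{slug}.nwk").write_text(
            _annotated_newick(tree, table)
        )
    origins = summarize_origins(report, config.threshold)
    with open(out / "origins.tsv", "w") as fh:
        fh.write("class\tearliest_clade\n")
        for char, clade in origins.items():
            fh.write(f"{char}\t{clade if clade is not None else 'none'}\n")

    manifest = {
        "package": "pherotrace",
        "version": __version__,
        "inputs": {
            "tree": {"path": str(config.tree_path), "sha256": _sha256(config.tree_path)},
        },
        "settings": {
            "threshold": config.threshold,
            "q_bounds": list(config.q_bounds),
            "criterion": {
                "alpha": config.criterion.alpha,
                "min_fold": config.criterion.min_fold,
                "min_detect_frac": config.criterion.min_detect_frac,
            },
            "seed": config.seed,
        },
    }
    for key, path in (("matrix", config.matrix_path),
                      ("profiles", config.profiles_path),
                      ("clades", config.clades_path)):
        if path is not None:
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("wrote reports for %d characters to %s",
                len(report.per_character), out)
    return report


def _annotated_newick(tree, table) -> str:
    """Newick with node comments carrying the percent 'present' proportion."""
    from .tree import PhyloNode

    def fmt(node: PhyloNode) -> str:
        if node.is_tip:
            label = node.label
            if any(ch in label for ch in " ()[]{}:;,'"):
                label = "'" + label.replace("'", "''") + "'"
            body = label
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        pct = 100.0 * table.present(node.id)
        body += f"[&present={pct:.1f}]"
        if not node.is_root:
            body += f":{node.length:g}"
        return body

    return fmt(tree.root) + ";"


def summarize_origins(
    report: CladeReport, threshold: float = 0.50
) -> dict[str, Optional[str]]:
    """Earliest (most inclusive) named clade where each class is likely present.

    Clades are taken in the report's column order, which runs from most to
    least inclusive; the first cell strictly above the threshold wins.
    Classes below the threshold everywhere map to ``None``.
    """
    cut = threshold * 100.0
    origins: dict[str, Optional[str]] = {}
    for char in report.percent.index:
        origins[char] = None
        for clade in report.percent.columns:
            if report.percent.loc[char, clade] > cut:
                origins[char] = clade
                break
    return origins
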
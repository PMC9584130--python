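"""End-to-end orchestration: changes -> screen -> blocks -> PLSPM -> groups -> models.

Every stage writes a plain CSV/JSON artifact; all randomness flows from
named per-stage seeds in the config, so a fixed config gives a
byte-identical artifact set.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import blocks as bk
from . import changes as ch
from . import heterogeneity as het
from . import models as md
from . import plspm as pl
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_phase_table", "read_blocks"]


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run.

    File paths may be None when ``synthetic`` is set, in which case the
    generator supplies the cohort.
    """

    baseline_path: str | None = None
    chronic_path: str | None = None
    blocks_path: str | None = None  # user-supplied block structure (optional)
    out_dir: str = "phenoblocks_out"
    synthetic: bool = False
    n_subjects: int = 883
    knn: int = 7
    laplacian: str = "sym"
    paired_test: str = "signed-rank"
    plspm_tol: float = 1e-6
    plspm_max_iter: int = 100
    plspm_scheme: str = "centroid"
    target_trait: str = "SPO2"
    kmax: int = 10
    index_roster: list[str] | None = None
    folds: int = 10
    seeds: dict[str, int] = field(
        default_factory=lambda: {"cohort": 0, "blocks": 0, "kmeans": 0, "cv": 0}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_phase_table(path: str | Path) -> pd.DataFrame:
    """Read a subjects x traits CSV whose first column is the subject id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phase table not found: {path}")
    return pd.read_csv(path, index_col=0)


def read_blocks(path: str | Path) -> bk.BlockStructure:
    """Read a (trait, block_id) CSV into a block structure."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"block structure not found: {path}")
    return bk.BlockStructure.from_frame(pd.read_csv(path))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages, writing one artifact per stage into ``out_dir``.

    Returns a mapping of artifact name to written path.  A stage failure
    raises with the stage name; artifacts written before the failure are
    retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _write(name: str, fname: str, obj) -> None:
        path = out / fname
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path)
        else:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2)
        artifacts[name] = path
        logger.info("stage %s -> %s", name, path)

    stage = "input"
    try:
        if config.synthetic:
            cfg = syn.default_config(config.n_subjects, seed=config.seeds["cohort"])
            baseline, chronic, true_blocks, true_groups = syn.generate_cohort(cfg)
            _write("baseline", "baseline.csv", baseline)
            _write("chronic", "chronic.csv", chronic)
            _write("true_blocks", "true_blocks.csv",
                   true_blocks.to_frame().set_index("trait"))
            _write("true_groups", "true_groups.csv", true_groups.to_frame())
        else:
            baseline = read_phase_table(config.baseline_path)
            chronic = read_phase_table(config.chronic_path)

        stage = "changes"
        delta = ch.compute_changes(baseline, chronic)
        _write("delta", "delta.csv", delta)

        stage = "screen"
        screen = ch.screen_traits(baseline, chronic, variant=config.paired_test)
        _write("screen", "screen.csv", screen.set_index("trait"))

        stage = "blocks"
        if config.blocks_path:
            structure = read_blocks(config.blocks_path)
            emb = None
        else:
            structure, emb = bk.discover_blocks(
                delta, k_nn=config.knn, seed=config.seeds["blocks"]
            )
            spectrum = pd.DataFrame(
                {"eigenvalue": emb.eigenvalues},
                index=pd.RangeIndex(1, len(emb.eigenvalues) + 1, name="index"),
            )
            _write("spectrum", "spectrum.csv", spectrum)
        _write("blocks", "blocks.csv", structure.to_frame().set_index("trait"))

        stage = "plspm"
        aligned, flipped = pl.align_signs(delta, structure)
        model = pl.build_default_path_model(structure, config.target_trait)
        fit = pl.fit_plspm(
            aligned, model, tol=config.plspm_tol, max_iter=config.plspm_max_iter
        )
        _write("scores", "scores.csv", fit.lv_scores)
        _write("loadings", "loadings.csv", fit.loadings.rename("loading").to_frame())
        _write("unidim", "unidim.csv", pl.unidimensionality_report(aligned, structure))

        stage = "groups"
        k, votes = het.select_k_majority(
            fit.lv_scores, range(2, config.kmax + 1),
            indices=config.index_roster, seed=config.seeds["kmeans"],
        )
        assign = het.kmeans_subjects(fit.lv_scores, k, seed=config.seeds["kmeans"])
        _write("labels", "labels.csv", assign.labels.to_frame())
        sil, sil_mean = het.silhouette_report(fit.lv_scores, assign.labels)
        report = {
            "selected_k": k,
            "votes": {n: (int(v) if v is not None else None) for n, v in votes.items()},
            "group_sizes": assign.sizes.to_dict(),
            "silhouette_mean": sil_mean,
            "sign_flipped_traits": flipped,
        }
        if k == 2:
            lv_tests = het.group_lv_tests(fit.lv_scores, assign.labels)
            _, comparisons = het.groupwise_correlation_matrices(
                fit.lv_scores, assign.labels
            )
            _write("lv_tests", "lv_tests.csv", lv_tests)
            _write("corr_comparisons", "corr_comparisons.csv",
                   comparisons.set_index(["lv_a", "lv_b"]))
        _write("hetero", "hetero.json", report)

        stage = "models"
        target_lv = f"LV{structure.assignment[config.target_trait]}"
        comparison = md.compare_model_fits(
            delta, fit.lv_scores,
            response=config.target_trait, response_lv=target_lv,
            folds=config.folds, seed=config.seeds["cv"],
        )
        _write("comparison", "comparison.json", comparison.to_dict())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
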
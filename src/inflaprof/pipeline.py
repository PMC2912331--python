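"""End-to-end orchestration: config validation, staged execution, manifest.

``run_pipeline`` drives the whole procedure — signature identification for
every reference population, the case/control contrast, the inflammation
profile, and attribution of top induced transcripts — writing TSV/JSON
reports plus a machine-readable manifest (parameters, package version, input
checksums, per-stage timings). Outputs are deterministic given inputs and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .attribution import attribute, top_induced
from .io import ExpressionMatrix, read_matrix, write_matrix
from .profiles import build_profile, class_summary
from .signatures import SignatureSet, SignatureThresholds, identify_signatures, signature_overlap
from .stats import contrast

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Population matrices are TSV files; ``populations`` maps population id to
    its matrix path, ``classes`` maps population id to a class label
    (defaults to "unknown"). Thresholds mirror the documented defaults:
    signature gate p_adj_max = 1e-4 and fc_min = 16, profile alpha = 0.05,
    k_top = 500 attribution pool, k_screen = 200 predictor list.
    """

    reference: str
    populations: dict[str, str]
    case_matrix: str
    case_group: str
    control_group: str
    out_dir: str
    classes: dict[str, str] = field(default_factory=dict)
    case_samples: list[str] = field(default_factory=list)
    control_samples: list[str] = field(default_factory=list)
    p_adj_max: float = 1e-4
    fc_min: float = 16.0
    alpha: float = 0.05
    k_top: int = 500
    k_screen: int = 200
    method: str = "moderated"
    linkage: str = "average"
    overlap_metric: str = "min"
    class_filter: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.fc_min <= 1.0:
            raise PipelineError(f"config: fc_min must exceed 1, got {self.fc_min}")
        if not (0.0 < self.p_adj_max < 1.0):
            raise PipelineError(f"config: p_adj_max must lie in (0,1), got {self.p_adj_max}")
        if not (0.0 < self.alpha < 1.0):
            raise PipelineError(f"config: alpha must lie in (0,1), got {self.alpha}")
        if self.k_top < 1 or self.k_screen < 1:
            raise PipelineError("config: k_top and k_screen must be >= 1")
        if self.method not in ("moderated", "ordinary"):
            raise PipelineError(f"config: unknown method {self.method!r}")
        if not self.populations:
            raise PipelineError("config: at least one population matrix required")
        for label, path in [("reference", self.reference), ("case_matrix", self.case_matrix)] + [
            (f"population {pid}", p) for pid, p in self.populations.items()
        ]:
            if not Path(path).exists():
                raise PipelineError(f"config: {label} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run signatures -> contrast -> profile -> attribution, writing reports.

    Returns the output directory. Raises :class:`PipelineError` with the
    stage name on any failure.
    """
    config.validate()
    out = Path(config.out_dir)
    for sub in ("signatures", "profile", "attribution", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _Timer()

    thresholds = SignatureThresholds(config.p_adj_max, config.fc_min)

    with stage("load"):
        reference = read_matrix(config.reference)
        case = read_matrix(config.case_matrix)
        pop_matrices = {pid: read_matrix(p) for pid, p in config.populations.items()}

    with stage("signatures"):
        sets: list[SignatureSet] = []
        for pid, mat in pop_matrices.items():
            sig = identify_signatures(
                mat,
                reference,
                thresholds,
                population_id=pid,
                class_label=config.classes.get(pid, "unknown"),
                method=config.method,
            )
            sig.write_tsv(out / "signatures" / f"{pid}.tsv")
            sets.append(sig)
        if len(sets) >= 2:
            overlap = signature_overlap(sets, metric=config.overlap_metric)
            overlap.matrix.to_csv(out / "reports" / "signature_overlap.tsv", sep="\t",
                                  float_format="%.6g")

    with stage("contrast"):
        if config.case_samples and config.control_samples:
            g_case, g_ctrl = config.case_samples, config.control_samples
        else:
            g_case = case.samples_in_group(config.case_group)
            g_ctrl = case.samples_in_group(config.control_group)
        de = contrast(case, g_ctrl, g_case, method=config.method)
        de.to_csv(out / "reports" / "contrast.tsv", sep="\t", float_format="%.10g")

    with stage("profile"):
        label = f"{config.case_group}_vs_{config.control_group}"
        profile = build_profile(sets, de, alpha=config.alpha, contrast_label=label)
        profile.write_tsv(out / "profile" / "profile.tsv")
        profile.write_json(out / "profile" / "profile.json")
        class_summary(profile).to_csv(out / "profile" / "class_summary.tsv", sep="\t",
                                      float_format="%.6g")

    with stage("attribution"):
        top = top_induced(de, config.k_top)
        filt = set(config.class_filter) or None
        result = attribute(top, profile, sets, class_filter=filt)
        result.write_tsv(out / "attribution" / "assignments.tsv")
        result.write_json(out / "attribution" / "summary.json")

    manifest = {
        "package": "inflaprof",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {
            "reference": _sha256(config.reference),
            "case_matrix": _sha256(config.case_matrix),
            "populations": {pid: _sha256(p) for pid, p in config.populations.items()},
        },
        "timings_sec": timings,
        "n_significant": len(profile.significant_ids),
        "significant_populations": profile.significant_ids,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
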
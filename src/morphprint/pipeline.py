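"""End-to-end workflow orchestration with run manifests.

``run_derive`` fits the control age model, preprocesses both cohorts and
writes the screening statistics plus the bilateral fingerprint;
``run_score`` applies a stored fingerprint to a new cohort and writes
per-subject profiles and the at-risk classification.  Every run leaves a
JSON manifest listing input/output digests, the seed(s) involved and stage
timings, so two runs are diffable and deterministic stages reproduce
digests exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import registry as reg
from .errors import ValidationError
from .fingerprint import Fingerprint, build_fingerprint, compare_groups, region_stats_frame
from .io_morphometry import MorphometryTable, read_long_tsv
from .preprocess import fit_age_model, preprocess_pipeline
from .scoring import build_control_reference, classify_cohort, profiles_to_tsv, score_cohort

logger = logging.getLogger(__name__)

REGISTRY_VERSION = "default-89-v1"


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    stage: str
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    registry_version: str = REGISTRY_VERSION
    seed: int | None = None

    def add_input(self, path: str | Path) -> None:
        path = Path(path)
        self.inputs[path.name] = _sha256(path)

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = _sha256(path)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()

    def write(self, path: str | Path) -> None:
        payload = {
            "stage": self.stage,
            "registry_version": self.registry_version,
            "seed": self.seed,
            "config": self.config,
            "config_hash": self.config_hash(),
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings_s": self.timings,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


class _Timer:
    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest, self.stage = manifest, stage

    def __enter__(self):
        self.start = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.timings[self.stage] = round(time.perf_counter() - self.start, 4)
        return False


def derive_fingerprint(
    controls: MorphometryTable,
    cases: MorphometryTable,
    alpha: float = 0.05,
    welch: bool = False,
    registry: reg.RegionRegistry | None = None,
) -> tuple[Fingerprint, list, "MorphometryTable"]:
    """Fit age model on controls, preprocess both cohorts, screen and filter.

    Returns (fingerprint, region stats, normalized controls) so callers can
    reuse the normalized control table for reference building.
    """
    registry = registry or reg.build_default_registry()
    model = fit_age_model(controls)
    controls_n = preprocess_pipeline(controls, model, registry)
    cases_n = preprocess_pipeline(cases, model, registry)
    stats = compare_groups(cases_n, controls_n, welch=welch)
    return build_fingerprint(stats, alpha=alpha), stats, controls_n


def run_derive(
    controls_path: str | Path,
    cases_path: str | Path,
    out_dir: str | Path,
    alpha: float = 0.05,
    welch: bool = False,
) -> dict:
    """CLI backend: derive a fingerprint from two raw long-TSV cohorts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = reg.build_default_registry()
    manifest = RunManifest(stage="derive", config={"alpha": alpha, "welch": welch})
    manifest.add_input(controls_path)
    manifest.add_input(cases_path)

    with _Timer(manifest, "read"):
        controls = read_long_tsv(controls_path, registry)
        cases = read_long_tsv(cases_path, registry)
    logger.info("derive: read %d controls, %d cases", controls.n_subjects(), cases.n_subjects())
    if set(controls.subjects["group"]) != {"control"}:
        raise ValidationError("controls table must contain only group=control subjects")

    with _Timer(manifest, "fit"):
        model = fit_age_model(controls)
        controls_n = preprocess_pipeline(controls, model, registry)
        cases_n = preprocess_pipeline(cases, model, registry)
    with _Timer(manifest, "screen"):
        stats = compare_groups(cases_n, controls_n, welch=welch)
        fp = build_fingerprint(stats, alpha=alpha)
    logger.info(
        "derive: %d tests, %d fingerprint entries (%d regions)",
        len(stats), fp.entry_count(), fp.region_count(),
    )

    with _Timer(manifest, "write"):
        model.to_tsv(out_dir / "age_model.tsv")
        region_stats_frame(stats).to_csv(out_dir / "region_stats.tsv", sep="\t", index=False)
        fp.to_tsv(out_dir / "fingerprint.tsv")
        summary = fp.summary(registry)
        (out_dir / "fingerprint_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    for name in ("age_model.tsv", "region_stats.tsv", "fingerprint.tsv",
                 "fingerprint_summary.json"):
        manifest.add_output(out_dir / name)
    manifest.write(out_dir / "manifest.json")
    return summary


def run_score(
    fingerprint_path: str | Path,
    controls_path: str | Path,
    cohort_path: str | Path,
    out_dir: str | Path,
    z_threshold: float = 2.0,
    basis: str = "entries",
    leave_one_out: bool = False,
) -> dict:
    """CLI backend: score a cohort against a stored fingerprint.

    The control table is used both to refit the age model (the same
    preprocessing the fingerprint derivation applied) and to build the
    normative reference and the control count distribution.
    ``leave_one_out`` switches the controls' self-scoring to
    leave-one-out z-scores (less biased cutoff).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = reg.build_default_registry()
    manifest = RunManifest(
        stage="score",
        config={"z_threshold": z_threshold, "basis": basis, "leave_one_out": leave_one_out},
    )
    for path in (fingerprint_path, controls_path, cohort_path):
        manifest.add_input(path)

    with _Timer(manifest, "read"):
        fp = Fingerprint.from_tsv(fingerprint_path)
        controls = read_long_tsv(controls_path, registry)
        cohort = read_long_tsv(cohort_path, registry)
    if cohort.n_subjects() == 0:
        raise ValidationError("cohort table has no subjects")
    if len(fp) == 0:
        raise ValidationError("fingerprint is empty; nothing to score")

    with _Timer(manifest, "preprocess"):
        model = fit_age_model(controls)
        controls_n = preprocess_pipeline(controls, model, registry)
        cohort_n = preprocess_pipeline(cohort, model, registry)
    with _Timer(manifest, "score"):
        ref = build_control_reference(controls_n, fp)
        case_profiles = score_cohort(cohort_n, fp, ref, z_threshold=z_threshold)
        control_profiles = score_cohort(
            controls_n, fp, ref, z_threshold=z_threshold, leave_one_out=leave_one_out
        )
        classification = classify_cohort(case_profiles, control_profiles, basis=basis)

    with _Timer(manifest, "write"):
        ref.to_tsv(out_dir / "control_reference.tsv")
        profiles_to_tsv(case_profiles, out_dir / "profiles.tsv")
        counts = classification.cases.copy()
        counts.to_csv(out_dir / "classification.tsv", sep="\t", index=False)
        summary = classification.summary()
        (out_dir / "classification_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        (out_dir / "summary.txt").write_text(
            "at-risk classification\n"
            f"  cutoff (control mean + 2 SD): {classification.cutoff:.2f}\n"
            f"  cohort n:                     {classification.n}\n"
            f"  n at risk:                    {classification.n_at_risk}\n"
            f"  percent at risk:              {classification.percent_at_risk:.1f}%\n"
        )
    for name in ("control_reference.tsv", "profiles.tsv", "classification.tsv",
                 "classification_summary.json", "summary.txt"):
        manifest.add_output(out_dir / name)
    manifest.write(out_dir / "manifest.json")
    return summary
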
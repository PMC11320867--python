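"""Cohort-level aggregation and end-to-end pipeline orchestration.

Summaries follow the mean / median / 5th-95th percentile reporting style
used for structure-set congruence studies. Two pipelines are provided:

* :func:`run_commissioning` — per-role congruence comparison between a
  reference and a test structure set for each patient, with skip-and-count
  handling of missing roles and bilateral-structure pairing;
* :func:`run_validation` — the full artefact-impact analysis on a cohort
  of phantoms: thickness estimation, margin recommendation, target
  construction for both pathways, and per-fraction coverage results
  averaged within each phantom before cohort aggregation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .artefacts import coverage_analysis, estimate_sfd_thickness, margin_recommendation
from .errors import ValidationError
from .grids import BinaryStructure, resample_to_grid
from .margins import MarginPolicy, build_targets
from .metrics import compare_structures
from .phantom import Phantom

log = logging.getLogger("sctqa")

#: Structures reported once per side; a patient contributes them only when
#: both sides are present in both structure sets.
BILATERAL_ROLES = ("cochlea", "hippocampus", "optic_nerve")
_SIDES = ("_left", "_right")


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean: float
    median: float
    p5: float
    p95: float
    units: str


def summarize(values: Sequence[float], units: str = "") -> CohortSummary:
    """Mean, median and linear-interpolation 5/95 percentiles."""
    if len(values) == 0:
        raise ValidationError("cannot summarize an empty list")
    arr = np.asarray(values, dtype=float)
    return CohortSummary(
        n=len(arr),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        p5=float(np.percentile(arr, 5)),
        p95=float(np.percentile(arr, 95)),
        units=units,
    )


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _expand_bilateral(roles: Sequence[str]) -> tuple[list[str], set[str]]:
    expanded: list[str] = []
    bilateral: set[str] = set()
    for role in roles:
        if role in BILATERAL_ROLES:
            sided = [role + s for s in _SIDES]
            expanded.extend(sided)
            bilateral.update(sided)
        else:
            expanded.append(role)
    return expanded, bilateral


@dataclass
class CommissioningReport:
    rows: pd.DataFrame           # one row per compared structure pair
    summaries: pd.DataFrame      # per-role DSC / AHD cohort summaries
    band_counts: pd.DataFrame    # per-role congruence-band tallies
    skipped: pd.DataFrame        # pairs excluded and why
    meta: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(outdir / "congruence.csv", index=False)
        self.summaries.to_csv(outdir / "congruence_summary.csv", index=False)
        self.band_counts.to_csv(outdir / "band_counts.csv", index=False)
        self.skipped.to_csv(outdir / "skipped_pairs.csv", index=False)
        (outdir / "report_meta.json").write_text(json.dumps(self.meta, indent=2, sort_keys=True) + "\n")


def run_commissioning(
    pairs: Sequence[tuple[Mapping[str, BinaryStructure], Mapping[str, BinaryStructure]]],
    roles: Sequence[str],
    ahd_combine: str = "max",
) -> CommissioningReport:
    """Compare reference and test structure sets for a cohort.

    ``pairs`` holds one ``(reference_set, test_set)`` mapping pair per
    patient, keyed by role. A role missing on either side is skipped and
    counted, never imputed. Bilateral roles (cochlea, hippocampus, optic
    nerve, stored with ``_left``/``_right`` suffixes) contribute only when
    both sides exist in both sets. Cross-grid pairs are resampled onto the
    reference grid.
    """
    expanded, bilateral = _expand_bilateral(roles)
    rows, skipped = [], []
    for patient, (ref_set, test_set) in enumerate(pairs):
        present = {
            r for r in expanded if r in ref_set and r in test_set
        }
        for role in expanded:
            if role not in present:
                skipped.append({"patient": patient, "role": role, "reason": "missing"})
                log.warning("patient %d: role %r missing on one side, skipped", patient, role)
                continue
            if role in bilateral:
                base = role.rsplit("_", 1)[0]
                if not all(base + s in present for s in _SIDES):
                    skipped.append({"patient": patient, "role": role,
                                    "reason": "contralateral side missing"})
                    log.warning("patient %d: %r excluded, contralateral side missing",
                                patient, role)
                    continue
            res = compare_structures(ref_set[role], test_set[role], ahd_combine=ahd_combine)
            rows.append({"patient": patient, "role": role, **asdict(res)})
    if not rows and not skipped:
        raise ValidationError("no overlapping roles between the structure sets")
    rows_df = pd.DataFrame(rows)
    if rows_df.empty:
        raise ValidationError("all requested role pairs were missing")

    summaries = []
    for role, grp in rows_df.groupby("role", sort=True):
        for metric, units in (("dsc", ""), ("ahd_mm", "mm")):
            s = summarize(grp[metric].tolist(), units)
            summaries.append({"role": role, "metric": metric, **asdict(s)})
    band_counts = (
        rows_df.groupby(["role", "band"], sort=True).size().reset_index(name="count")
    )
    meta = {
        "version": __version__,
        "config_hash": _config_hash({"roles": list(roles), "ahd_combine": ahd_combine}),
        "n_patients": len(pairs),
        "n_pairs_compared": len(rows_df),
        "n_pairs_skipped": len(skipped),
    }
    return CommissioningReport(
        rows=rows_df.drop(columns=["name"]),
        summaries=pd.DataFrame(summaries),
        band_counts=band_counts,
        skipped=pd.DataFrame(skipped, columns=["patient", "role", "reason"]),
        meta=meta,
    )


@dataclass
class ValidationReport:
    coverage: pd.DataFrame       # one row per phantom x fraction x pathway
    phantom_means: pd.DataFrame  # fraction-averaged volumes per phantom/pathway
    thickness: pd.DataFrame      # per-artefact thickness estimates
    summaries: pd.DataFrame      # cohort summaries of uncovered volumes
    margin_recommendation_mm: float
    meta: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.coverage.to_csv(outdir / "coverage.csv", index=False)
        self.phantom_means.to_csv(outdir / "coverage_phantom_means.csv", index=False)
        self.thickness.to_csv(outdir / "thickness.csv", index=False)
        self.summaries.to_csv(outdir / "validation_summary.csv", index=False)
        (outdir / "report_meta.json").write_text(json.dumps(self.meta, indent=2, sort_keys=True) + "\n")


def run_validation(
    cohort: Iterable[Phantom],
    policy: MarginPolicy = MarginPolicy(),
) -> ValidationReport:
    """Artefact-impact analysis over a phantom cohort.

    For every phantom: SFD thickness is estimated from the paired device
    delineations; both target pathways are built on the sCT grid from the
    ground-truth CTV, brain and sCT bone; each fraction's CBCT bone is
    resampled onto the sCT grid and the coverage pipeline is run for the
    adjusted and non-adjusted pathway, always with the adjusted PTV as
    control region. Volumes are averaged over fractions within a phantom,
    then summarized over the cohort.
    """
    cov_rows, thick_rows = [], []
    thicknesses: list[float] = []
    n_phantoms = 0
    for pid, ph in enumerate(cohort):
        n_phantoms += 1
        truth = ph.truth
        for aid, art in enumerate(truth.artefacts):
            if art.sfd_ct is None:
                continue
            est = estimate_sfd_thickness(art.sfd_ct, art.sfd_sct)
            thicknesses.append(est)
            thick_rows.append({
                "phantom": pid, "artefact": aid, "artefact_type": art.artefact_type,
                "true_thickness_mm": art.thickness_mm, "estimated_thickness_mm": est,
            })
        if not truth.bone_cbct:
            log.warning("phantom %d has no CBCT fractions, skipped from coverage", pid)
            continue
        targets = build_targets(truth.ctv_sct, truth.brain_sct, truth.bone_sct, policy)
        ptv_a, ptv_na = targets["PTV_a"], targets["PTV_na"]
        for i, b_cbct in enumerate(truth.bone_cbct, start=1):
            b_cbct_sct = resample_to_grid(b_cbct, truth.bone_sct.grid)
            for pathway, ptv_eval in (("adjusted", ptv_a), ("non_adjusted", ptv_na)):
                res = coverage_analysis(
                    truth.bone_sct, b_cbct_sct, ptv_a, ptv_eval,
                    pathway, fraction_index=i,
                )
                cov_rows.append({"phantom": pid, **asdict(res)})

    if not cov_rows:
        raise ValidationError("no phantom contributed coverage results")
    coverage = pd.DataFrame(cov_rows)
    phantom_means = (
        coverage.groupby(["phantom", "pathway"], sort=True)[
            ["iv_sct_cc", "iv_cbct_cc", "v_a_cc", "v_uncov_cc", "uncovered_fraction_pct"]
        ].mean().reset_index()
    )
    summaries = []
    for pathway, grp in phantom_means.groupby("pathway", sort=True):
        for metric, units in (("v_uncov_cc", "cc"), ("uncovered_fraction_pct", "%"),
                              ("v_a_cc", "cc")):
            s = summarize(grp[metric].tolist(), units)
            summaries.append({"pathway": pathway, "metric": metric, **asdict(s)})

    rec = margin_recommendation(thicknesses) if thicknesses else float("nan")
    meta = {
        "version": __version__,
        "config_hash": _config_hash(asdict(policy)),
        "n_phantoms": n_phantoms,
        "margin_recommendation_mm": rec,
    }
    return ValidationReport(
        coverage=coverage,
        phantom_means=phantom_means,
        thickness=pd.DataFrame(thick_rows),
        summaries=pd.DataFrame(summaries),
        margin_recommendation_mm=rec,
        meta=meta,
    )
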
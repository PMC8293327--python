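"""Retrospective truncation of dynamic series and the paired fit study.

A full time course (FTC) is truncated into abbreviated time courses
(ATCs); ATC_n keeps the baseline block plus the first n post-injection
frames.  Both kinetic models are fit to the FTC and to every ATC of the
dataset's schedule, the physiological filter is applied voxelwise, and
the paired (ATC, FTC) estimates are assembled in tidy form.  The FTC fit
is the gold standard: voxels that fail the filter there are dropped from
every comparison, while an ATC-level failure drops the voxel from that
ATC's comparison only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .protocols import PatientSpec
from .pk_models import fit_model
from .relaxometry import r1_to_concentration, signal_to_r1_series
from .synthetic_cohort import SyntheticPatient

__all__ = [
    "AtcSchedule",
    "DynamicSeries",
    "PairedEstimates",
    "build_atc_schedule",
    "atc_duration_min",
    "truncate_series",
    "run_truncation_study",
    "signal_to_concentration",
]

log = logging.getLogger(__name__)

# post-injection frame counts per (dataset, model); the Patlak windows
# stop early because the model assumes no washout
_SCHEDULES = {
    ("ACRIN", "SKT"): tuple(range(7, 19)),
    ("ACRIN", "Patlak"): tuple(range(2, 8)),
    ("single-site", "SKT"): tuple(range(13, 54, 8)),
    ("single-site", "Patlak"): tuple(range(5, 15)),
}


@dataclass(frozen=True)
class AtcSchedule:
    dataset: str
    model: str
    n_values: tuple[int, ...]
    dt: float  # s

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.n_values, self.n_values[1:])):
            raise ValueError("n_values must be strictly increasing")


@dataclass
class DynamicSeries:
    """A time grid with per-voxel curves and baseline metadata."""

    time_min: np.ndarray
    data: np.ndarray  # frames (x voxels)
    n_baseline: int
    voxel_ids: np.ndarray | None = None
    space: str = "concentration"  # or "signal"

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.time_min.shape[0]:
            raise ValueError("data and time grid must align on axis 0")
        if self.n_baseline > self.data.shape[0]:
            raise ValueError("baseline exceeds series length")

    @property
    def n_post_injection(self) -> int:
        return self.data.shape[0] - self.n_baseline


@dataclass
class PairedEstimates:
    """Tidy voxelwise ATC-vs-FTC estimates for one patient and model."""

    patient_id: str
    model: str
    table: pd.DataFrame  # patient, model, atc_n, voxel, param, value_atc, value_ftc, kept
    n_removed_ftc: int = 0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_atc_schedule(dataset: str, model: str, dt: float | None = None) -> AtcSchedule:
    """The published truncation schedule for a dataset/model pair."""
    key = (dataset, model)
    if key not in _SCHEDULES:
        raise ValueError(
            f"unknown dataset/model pair {key!r}; valid: {sorted(_SCHEDULES)}"
        )
    if dt is None:
        dt = 15.0 if dataset == "ACRIN" else 7.27
    return AtcSchedule(dataset=dataset, model=model, n_values=_SCHEDULES[key], dt=dt)


def atc_duration_min(n: int, dt_s: float, ndigits: int = 2) -> float:
    """Post-injection scan time of ATC_n in minutes.

    The exact value ``n * dt / 60`` rounded once to ``ndigits`` for
    display (rounding an already-rounded value can flip the last digit).
    """
    if n < 1 or dt_s <= 0:
        raise ValueError("need n >= 1 and dt > 0")
    return round(n * dt_s / 60.0, ndigits)


def truncate_series(series: DynamicSeries, n: int) -> DynamicSeries:
    """Keep the baseline block plus the first ``n`` post-injection frames."""
    if n < 1 or n > series.n_post_injection:
        raise ValueError(
            f"n must be in [1, {series.n_post_injection}], got {n}"
        )
    stop = series.n_baseline + n
    return replace(
        series,
        time_min=series.time_min[:stop],
        data=series.data[:stop],
    )


def signal_to_concentration(
    signal,
    time_min,
    spec: PatientSpec,
    r10,
) -> np.ndarray:
    """Dynamic signal to concentration via SPGR inversion and relaxivity."""
    proto = spec.protocol
    series = signal_to_r1_series(
        signal, proto.n_baseline, r10, proto.tr, proto.flip_angle, time_min=time_min
    )
    if series.n_clamped:
        log.info("%d saturated frames clamped during inversion", series.n_clamped)
    return r1_to_concentration(series.r1, r10, proto.relaxivity_r1)


def _fit_voxel(model_key, curve, t, aif, rr, c_rr):
    if model_key == "skt":
        return fit_model("skt", curve, aif, t)
    if model_key == "patlak":
        return fit_model("patlak", curve, aif, t)
    if model_key == "rr_skt":
        return fit_model("rr_skt", curve, rr, t, c_rr=c_rr)
    return fit_model("rr_patlak", curve, rr, t, c_rr=c_rr)


def _model_key(dataset: str, model: str, use_rr: bool | None) -> str:
    """AIF-based models for the single-site dataset, reference-region
    models for the multi-site dataset (which has no measured input)."""
    if use_rr is None:
        use_rr = dataset == "ACRIN"
    base = "skt" if model == "SKT" else "patlak"
    return f"rr_{base}" if use_rr else base


def run_truncation_study(
    patient: SyntheticPatient,
    model: str,
    schedule: AtcSchedule | None = None,
    use_noiseless: bool = False,
    use_rr: bool | None = None,
) -> PairedEstimates:
    """Fit FTC and every scheduled ATC for one patient; pair voxelwise.

    The dynamic signal is converted to concentration once on the full
    grid (reusing the known pre-contrast R10 for every ATC); truncation
    then slices that concentration series, so ATC data are bitwise
    prefixes of longer ATCs.
    """
    spec = patient.spec
    dataset = spec.protocol.name
    if schedule is None:
        schedule = build_atc_schedule(dataset, model, dt=spec.protocol.dt)
    mkey = _model_key(dataset, model, use_rr)
    params_of = ("ktrans", "ve") if model == "SKT" else ("ktrans",)

    signal = patient.signal_noiseless if use_noiseless else patient.dynamic_signal
    conc = signal_to_concentration(
        signal, patient.time_min, spec, patient.truth.r10[None, :]
    )
    series = DynamicSeries(
        time_min=patient.time_min,
        data=conc,
        n_baseline=spec.protocol.n_baseline,
        voxel_ids=patient.truth.voxel_ids,
    )

    n_values = [n for n in schedule.n_values if n <= series.n_post_injection]
    if len(n_values) < len(schedule.n_values):
        log.warning(
            "patient %s: schedule clipped to %d ATCs (series too short)",
            spec.patient_id,
            len(n_values),
        )

    def fit_all(sub: DynamicSeries) -> pd.DataFrame:
        rows = []
        t = sub.time_min
        c_rr = patient.c_rr[: t.size]
        for j, vox in enumerate(patient.truth.voxel_ids):
            res = _fit_voxel(mkey, sub.data[:, j], t, patient.aif, patient.rr, c_rr)
            rows.append(
                {
                    "voxel": vox,
                    "ktrans": res.params.ktrans,
                    "ve": res.params.ve if model == "SKT" else np.nan,
                    "converged": res.converged,
                    "in_range": res.in_physiological_range,
                }
            )
        return pd.DataFrame(rows)

    ftc = fit_all(series)
    keep_ftc = ftc["in_range"].to_numpy(bool)
    n_removed = int((~keep_ftc).sum())
    if n_removed:
        log.info("patient %s: %d voxels removed at FTC", spec.patient_id, n_removed)

    records = []
    for n in n_values:
        sub = truncate_series(series, n)
        atc = fit_all(sub)
        keep = keep_ftc & atc["in_range"].to_numpy(bool)
        for p in params_of:
            for j in range(len(atc)):
                records.append(
                    {
                        "patient": spec.patient_id,
                        "model": model,
                        "atc_n": n,
                        "voxel": atc["voxel"].iloc[j],
                        "param": p,
                        "value_atc": atc[p].iloc[j],
                        "value_ftc": ftc[p].iloc[j],
                        "kept": bool(keep[j]),
                    }
                )
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "patient", "model", "atc_n", "voxel", "param",
            "value_atc", "value_ftc", "kept",
        ],
    )
    return PairedEstimates(
        patient_id=spec.patient_id,
        model=model,
        table=table,
        n_removed_ftc=n_removed,
    )
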
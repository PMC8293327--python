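"""Acquisition presets and patient cohorts.

Two pulse-sequence presets are bundled: a multi-site breast trial acquired
at 1.5 T with 15 s temporal resolution and a 90 degree flip angle
("ACRIN"), and a single-site community protocol acquired at 3 T with
7.27 s resolution and a 6 degree flip angle ("single-site").  Every other
module takes its timing and signal-model constants from an
:class:`AcquisitionProtocol` so that unit conventions live in one place.

Unit conventions
----------------
Time grids are carried in minutes and transfer constants in 1/min;
repetition/echo times stay in milliseconds and relaxation rates in 1/s,
converted explicitly at the relaxometry boundary; concentrations are mM.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "AcquisitionProtocol",
    "PatientSpec",
    "acrin_preset",
    "single_site_preset",
    "table1_cohort",
    "protocol_to_yaml",
    "protocol_from_yaml",
    "cohort_to_csv",
    "cohort_from_csv",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Pulse-sequence and timing constants for one dynamic acquisition.

    Parameters
    ----------
    name : str
        Preset label, e.g. ``"ACRIN"`` or ``"single-site"``.
    tr : float
        Repetition time in ms.
    te : float
        Echo time in ms.  Stored for provenance only; the SPGR signal
        model neglects T2* decay (TE << T2* in both presets).
    flip_angle : float
        Nominal excitation flip angle in degrees.
    dt : float
        Temporal resolution in seconds per dynamic frame.
    n_timepoints : int
        Total dynamic frames of a full-length series.
    n_baseline : int
        Pre-injection frames at the start of the series.
    relaxivity_r1 : float
        Contrast-agent longitudinal relaxivity in L/(mmol s).
    field_strength : float
        Main field in tesla (metadata).
    """

    name: str
    tr: float
    te: float
    flip_angle: float
    dt: float
    n_timepoints: int
    n_baseline: int
    relaxivity_r1: float
    field_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not (0 < self.flip_angle <= 90):
            raise ValueError(f"flip_angle must be in (0, 90], got {self.flip_angle}")
        if self.n_baseline < 0 or self.n_timepoints < self.n_baseline:
            raise ValueError(
                "need n_timepoints >= n_baseline >= 0, got "
                f"{self.n_timepoints} / {self.n_baseline}"
            )

    @property
    def dt_min(self) -> float:
        """Frame spacing in minutes."""
        return self.dt / 60.0

    @property
    def injection_min(self) -> float:
        """Time of contrast arrival: end of the baseline block, minutes."""
        return self.n_baseline * self.dt / 60.0

    def time_grid_min(self, n_frames: int | None = None):
        """Acquisition time grid in minutes, frame k at k*dt."""
        import numpy as np

        n = self.n_timepoints if n_frames is None else int(n_frames)
        return np.arange(n) * self.dt_min

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(**d)


@dataclass(frozen=True)
class PatientSpec:
    """One patient's acquisition: protocol, series length, SNR, diagnosis."""

    patient_id: str
    protocol: AcquisitionProtocol
    series_length: int
    snr: float
    diagnosis: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError(f"snr must be positive, got {self.snr}")
        if self.series_length < 1:
            raise ValueError("series_length must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"] = self.protocol.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PatientSpec":
        d = dict(d)
        d["protocol"] = AcquisitionProtocol.from_dict(d["protocol"])
        return cls(**d)


# Representative literature relaxivities for Gd chelates; neither protocol
# publishes one, so these are configurable defaults.
RELAXIVITY_1P5T = 4.5  # L/(mmol s)
RELAXIVITY_3T = 3.8


def acrin_preset(relaxivity_r1: float = RELAXIVITY_1P5T) -> AcquisitionProtocol:
    """Multi-site trial preset: 15 s frames, 90 deg flip, TR 100 ms.

    The dynamic scan starts simultaneously with contrast delivery, so
    there are no pre-injection baseline frames.  Series length varies per
    patient (14-37 frames); ``n_timepoints`` carries the cohort maximum.
    """
    return AcquisitionProtocol(
        name="ACRIN",
        tr=100.0,
        te=4.5,
        flip_angle=90.0,
        dt=15.0,
        n_timepoints=37,
        n_baseline=0,
        relaxivity_r1=relaxivity_r1,
        field_strength=1.5,
    )


def single_site_preset(relaxivity_r1: float = RELAXIVITY_3T) -> AcquisitionProtocol:
    """Single-site community preset: 7.27 s frames, 6 deg flip, TR 7.02 ms.

    66 frames total (about 8 min); the first eight frames (one minute) are
    acquired before the contrast injection.
    """
    return AcquisitionProtocol(
        name="single-site",
        tr=7.02,
        te=4.60,
        flip_angle=6.0,
        dt=7.27,
        n_timepoints=66,
        n_baseline=8,
        relaxivity_r1=relaxivity_r1,
        field_strength=3.0,
    )


# Cohort tables: (patient id, site, series length, SNR, diagnosis) for the
# multi-site trial; (patient id, SNR) for the single-site cohort, whose
# series length is always 66 frames.
_ACRIN_TABLE = [
    ("15", 1, 19, 14, 0),
    ("22", 1, 24, 22, 0),
    ("183", 1, 24, 26, 1),
    ("276", 1, 27, 26, 0),
    ("310", 1, 27, 24, 1),
    ("718", 1, 27, 25, 0),
    ("724", 3, 25, 16, 1),
    ("770", 1, 31, 30, 1),
    ("867", 2, 22, 18, 1),
    ("882", 2, 22, 22, 1),
    ("439", 3, 25, 22, 0),
    ("84", 1, 20, 13, 1),
    ("27", 1, 21, 28, 0),
    ("143", 1, 24, 33, 1),
    ("725", 1, 29, 6, 0),
]

_SINGLE_SITE_TABLE = [
    ("3", 19),
    ("6", 19),
    ("7", 26),
    ("8", 19),
    ("9", 14),
    ("11", 27),
    ("13", 24),
    ("15", 21),
    ("17", 26),
    ("18", 19),
    ("19", 8),
    ("22", 21),
    ("23", 25),
    ("26", 22),
    ("28", 27),
]

DATASETS = ("ACRIN", "single-site")


def table1_cohort(dataset: str) -> list[PatientSpec]:
    """The 15-patient cohort for one dataset.

    Multi-site entries carry a per-patient series length and SNR; the
    single-site entries carry a per-patient SNR with the full 66-frame
    series.  Single-site diagnoses are recorded as malignant (the cohort
    is locally advanced disease); this field is metadata only.
    """
    if dataset == "ACRIN":
        proto = acrin_preset()
        return [
            PatientSpec(pid, proto, length, snr, dx)
            for pid, _site, length, snr, dx in _ACRIN_TABLE
        ]
    if dataset == "single-site":
        proto = single_site_preset()
        return [
            PatientSpec(pid, proto, proto.n_timepoints, snr, 1)
            for pid, snr in _SINGLE_SITE_TABLE
        ]
    raise ValueError(f"unknown dataset {dataset!r}; expected one of {DATASETS}")


# ---------------------------------------------------------------------------
# serialization


def protocol_to_yaml(protocol: AcquisitionProtocol, path=None) -> str:
    text = yaml.safe_dump(protocol.to_dict(), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def protocol_from_yaml(source) -> AcquisitionProtocol:
    """Read a protocol from a YAML string, file path or open file."""
    if isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml")):
        with open(source) as fh:
            d = yaml.safe_load(fh)
    elif hasattr(source, "read"):
        d = yaml.safe_load(source)
    else:
        d = yaml.safe_load(source)
    return AcquisitionProtocol.from_dict(d)


def cohort_to_csv(cohort: Iterable[PatientSpec], path=None) -> str:
    rows = [
        {
            "patient_id": p.patient_id,
            "dataset": p.protocol.name,
            "series_length": p.series_length,
            "snr": p.snr,
            "diagnosis": p.diagnosis,
        }
        for p in cohort
    ]
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()


def cohort_from_csv(path, protocol: AcquisitionProtocol | None = None) -> list[PatientSpec]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    out = []
    for _, row in df.iterrows():
        proto = protocol
        if proto is None:
            proto = acrin_preset() if row["dataset"] == "ACRIN" else single_site_preset()
        out.append(
            PatientSpec(
                patient_id=str(row["patient_id"]),
                protocol=proto,
                series_length=int(row["series_length"]),
                snr=float(row["snr"]),
                diagnosis=int(row.get("diagnosis", 0)),
            )
        )
    return out
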
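"""Raw breath-sample records and their on-disk cohort container.

One measurement is a 90 s acquisition sampled at 30 Hz on 16 channels:
14 metal-oxide gas sensors operated in a thermal-cycling mode (3.5 s
heating / 5.5 s cooling) plus two synchronization channels (``SYNC_A``,
``SYNC_B``) that carry a square wave locked to the heater phase — a fixed
positive level while the heaters are on, zero while they cool.  A record
is therefore a 16 x 2700 matrix of ADC counts (43,200 values) together
with the subject's age, sex, smoking status and diagnosis label.

Cohorts are stored as a single ZIP container holding ``metadata.csv``
(one row per subject), ``records/<record_id>.csv`` (2700 rows x 16 named
columns, sensor order first, sync channels last) and a small
``provenance.json``.  Floats are written with 17 significant digits so
the container round-trips bit-exactly.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Tuple

import numpy as np
import pandas as pd

from .exceptions import CohortValidationError

SAMPLE_RATE_HZ = 30
RECORD_SECONDS = 90
N_SAMPLES = SAMPLE_RATE_HZ * RECORD_SECONDS  # 2700
N_SENSORS = 14
N_CHANNELS = 16
ADC_MAX = 4095.0  # 12-bit converter full scale

#: Gas-sensor channel order used throughout the package (channels 1-14),
#: followed by the two heater-phase synchronization channels.
SENSOR_NAMES: Tuple[str, ...] = (
    "MP503", "WSP2110", "MQ3", "MQ2", "MQ7", "MQ131", "MQ135",
    "MQ8", "MQ138", "TGS822", "TGS2602", "TGS2620", "TGS2600", "TGS2603",
)
SYNC_NAMES: Tuple[str, ...] = ("SYNC_A", "SYNC_B")
CHANNEL_NAMES: Tuple[str, ...] = SENSOR_NAMES + SYNC_NAMES

# Thermal-cycling geometry in samples (3.5 s heat + 5.5 s cool at 30 Hz).
HEAT_SAMPLES = 105
COOL_SAMPLES = 165
PERIOD_SAMPLES = HEAT_SAMPLES + COOL_SAMPLES  # 270

_SEX_VALUES = {"F", "M"}
_SMOKING_VALUES = {"no", "yes"}


@dataclass
class SensorRecord:
    """One subject's raw acquisition plus metadata.

    ``channels`` is a float64 array of shape (16, 2700) in ADC counts.
    ``sex`` is ``"F"``/``"M"`` and ``smoking`` is ``"no"``/``"yes"``;
    numeric encoding happens only at feature-extraction time.
    ``label`` is 1 for a confirmed malignancy, 0 for a control subject.
    """

    record_id: str
    channels: np.ndarray
    age: int
    sex: str
    smoking: str
    label: int
    sample_rate: float = float(SAMPLE_RATE_HZ)
    channel_names: Tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)

    def validate(self) -> List[str]:
        """Return a list of human-readable contract violations (empty if valid)."""
        rid = self.record_id
        problems: List[str] = []
        if self.channels.shape != (N_CHANNELS, N_SAMPLES):
            problems.append(
                f"{rid}: channels shape {self.channels.shape}, "
                f"expected ({N_CHANNELS}, {N_SAMPLES})"
            )
            return problems  # shape is wrong; further checks are meaningless
        if not np.all(np.isfinite(self.channels)):
            problems.append(f"{rid}: non-finite ADC values present")
        else:
            lo, hi = float(self.channels.min()), float(self.channels.max())
            if lo < 0.0 or hi > ADC_MAX:
                problems.append(
                    f"{rid}: ADC counts outside [0, {ADC_MAX:g}] "
                    f"(observed range [{lo:g}, {hi:g}])"
                )
            for ch in (14, 15):
                levels = np.unique(self.channels[ch])
                ok = (
                    levels.size == 2
                    and levels[0] == 0.0
                    and levels[1] > 0.0
                )
                if not ok:
                    problems.append(
                        f"{rid}: sync channel {self.channel_names[ch]} must take "
                        f"exactly the values {{0, positive constant}}; observed "
                        f"{levels.size} distinct level(s)"
                    )
        try:
            age_bad = not (float(self.age) > 0)
        except (TypeError, ValueError):
            age_bad = True
        if age_bad or (isinstance(self.age, float) and np.isnan(self.age)):
            problems.append(f"{rid}: age must be a positive number, got {self.age!r}")
        if self.label not in (0, 1):
            problems.append(f"{rid}: label must be 0 or 1, got {self.label!r}")
        if self.sex not in _SEX_VALUES:
            problems.append(f"{rid}: sex must be one of {sorted(_SEX_VALUES)}, got {self.sex!r}")
        if self.smoking not in _SMOKING_VALUES:
            problems.append(
                f"{rid}: smoking must be one of {sorted(_SMOKING_VALUES)}, got {self.smoking!r}"
            )
        return problems


@dataclass
class Cohort:
    """An ordered collection of :class:`SensorRecord` with provenance."""

    records: List[SensorRecord] = field(default_factory=list)
    provenance: str = "imported"
    generator_config_hash: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SensorRecord]:
        return iter(self.records)

    def validate(self) -> List[str]:
        problems: List[str] = []
        seen = set()
        for rec in self.records:
            if rec.record_id in seen:
                problems.append(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)
            problems.extend(rec.validate())
        return problems

    def raise_for_violations(self) -> None:
        problems = self.validate()
        if problems:
            raise CohortValidationError(problems)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def _record_csv(rec: SensorRecord) -> str:
    buf = io.StringIO()
    np.savetxt(
        buf,
        rec.channels.T,
        fmt="%.17g",
        delimiter=",",
        header=",".join(rec.channel_names),
        comments="",
    )
    return buf.getvalue()


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to a ZIP container at ``path``.

    Layout: ``metadata.csv`` with columns
    ``record_id,age,sex,smoking,label``, one ``records/<record_id>.csv``
    per subject (2700 rows, 16 named columns in sensor order then
    ``SYNC_A,SYNC_B``), and ``provenance.json``.
    """
    path = Path(path)
    meta = pd.DataFrame(
        {
            "record_id": [r.record_id for r in cohort.records],
            "age": [r.age for r in cohort.records],
            "sex": [r.sex for r in cohort.records],
            "smoking": [r.smoking for r in cohort.records],
            "label": [r.label for r in cohort.records],
        }
    )
    def _entry(name: str) -> zipfile.ZipInfo:
        # fixed timestamp so identical cohorts produce byte-identical containers
        info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        return info

    try:
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr(_entry("metadata.csv"), meta.to_csv(index=False))
            zf.writestr(
                _entry("provenance.json"),
                json.dumps(
                    {
                        "provenance": cohort.provenance,
                        "generator_config_hash": cohort.generator_config_hash,
                    },
                    indent=1,
                ),
            )
            for rec in cohort.records:
                zf.writestr(_entry(f"records/{rec.record_id}.csv"), _record_csv(rec))
    except OSError as exc:
        raise OSError(f"cannot write cohort container to {path}: {exc}") from exc


def read_cohort(path) -> Cohort:
    """Read a cohort container written by :func:`write_cohort`.

    Every record is validated against the raw-record contract; *all*
    violations are collected and raised together as
    :class:`~enose.exceptions.CohortValidationError`.
    """
    path = Path(path)
    problems: List[str] = []
    records: List[SensorRecord] = []
    with zipfile.ZipFile(path) as zf:
        with zf.open("metadata.csv") as fh:
            meta = pd.read_csv(fh, dtype={"record_id": str, "sex": str, "smoking": str})
        provenance, cfg_hash = "imported", ""
        if "provenance.json" in zf.namelist():
            prov = json.loads(zf.read("provenance.json"))
            provenance = prov.get("provenance", "imported")
            cfg_hash = prov.get("generator_config_hash", "")
        for row in meta.itertuples(index=False):
            rid = str(row.record_id)
            name = f"records/{rid}.csv"
            if name not in zf.namelist():
                problems.append(f"{rid}: record file {name} missing from container")
                continue
            with zf.open(name) as fh:
                # round_trip parser: bit-exact recovery of %.17g floats
                frame = pd.read_csv(fh, dtype=np.float64, float_precision="round_trip")
            channels = frame.to_numpy().T
            age = row.age
            if pd.isna(age):
                problems.append(f"{rid}: age missing from metadata")
                age = -1
            rec = SensorRecord(
                record_id=rid,
                channels=channels,
                age=int(age) if float(age) == int(age) else float(age),
                sex=str(row.sex),
                smoking=str(row.smoking),
                label=int(row.label),
                channel_names=tuple(frame.columns),
            )
            records.append(rec)
    cohort = Cohort(records=records, provenance=provenance, generator_config_hash=cfg_hash)
    problems.extend(cohort.validate())
    if problems:
        raise CohortValidationError(problems)
    return cohort
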
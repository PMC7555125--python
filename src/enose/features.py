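"""Feature construction: cycle-ratio features plus encoded metadata.

Each sensor's feature block is the elementwise ratio of its period-4 and
period-1 cooling segments (165 samples each), thinned to every 10th value
— 16 numbers per sensor.  Period 1 is the cooling phase during which the
breath sample is injected (still at baseline), period 4 is fully
equilibrated, so the ratio is the classic e-nose response ratio and is
invariant to per-sensor gain.  With age/100, a male indicator and a
smoker indicator appended, the input vector has

    14 sensors x 16 ratios + 3 metadata values = 227 dimensions.

No further normalization is applied: ratio features and the encoded
metadata are already of order one, which is what the sigmoid network
expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateSignalError
from .records import COOL_SAMPLES, N_SENSORS, SENSOR_NAMES, Cohort, SensorRecord
from .segmentation import SegmentedRecord, segment_record

N_RATIOS_PER_SENSOR = 16
N_METADATA = 3
N_FEATURES = N_SENSORS * N_RATIOS_PER_SENSOR + N_METADATA  # 227

DEFAULT_NUM_PERIOD = 4
DEFAULT_DEN_PERIOD = 1
DEFAULT_STRIDE = 10
DEFAULT_OFFSET = 0

_SEX_ENCODING = {"f": 0.0, "female": 0.0, "m": 1.0, "male": 1.0}
_SMOKING_ENCODING = {"no": 0.0, "non-smoker": 0.0, "yes": 1.0, "smoker": 1.0}


@dataclass
class FeatureVector:
    """One subject's 227-value network input plus identity and label."""

    values: np.ndarray
    label: int
    record_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(
                f"feature vector must have length {N_FEATURES}, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.record_id}: non-finite feature values")


def encode_metadata(age: float, sex: str, smoking: str) -> Tuple[float, float, float]:
    """Encode (age, sex, smoking) as (age/100, male?, smoker?).

    age/100 keeps the value of order one alongside the ratio features;
    sex and smoking are 0/1 indicators (male = 1, smoker = 1).
    """
    if not 0 < float(age) <= 150:
        raise ValueError(f"age must be in (0, 150], got {age!r}")
    try:
        sex_enc = _SEX_ENCODING[str(sex).lower()]
    except KeyError:
        raise ValueError(f"unknown sex category {sex!r}") from None
    try:
        smoking_enc = _SMOKING_ENCODING[str(smoking).lower()]
    except KeyError:
        raise ValueError(f"unknown smoking category {smoking!r}") from None
    return float(age) / 100.0, sex_enc, smoking_enc


def ratio_features(
    seg: SegmentedRecord,
    num_period: int = DEFAULT_NUM_PERIOD,
    den_period: int = DEFAULT_DEN_PERIOD,
) -> np.ndarray:
    """Elementwise period ratio per sensor, shape (14, 165).

    ``num_period`` and ``den_period`` are 1-based complete-cycle indices.
    A zero anywhere in the denominator segment means a sensor sat at the
    ADC floor and the record is unusable -> :class:`DegenerateSignalError`.
    """
    for name, p in (("num_period", num_period), ("den_period", den_period)):
        if not 1 <= p <= seg.n_cycles:
            raise ValueError(
                f"{name}={p} outside the available cycles 1..{seg.n_cycles}"
            )
    num = seg.cooling_segments[:, num_period - 1, :]
    den = seg.cooling_segments[:, den_period - 1, :]
    zero = np.argwhere(den == 0.0)
    if zero.size:
        s, i = zero[0]
        raise DegenerateSignalError(
            f"{seg.record_id}: sensor {SENSOR_NAMES[int(s)]} has a zero in its "
            f"period-{den_period} cooling segment at sample {int(i)} (ADC floor)"
        )
    return num / den


def downsample(
    ratios: np.ndarray,
    stride: int = DEFAULT_STRIDE,
    offset: int = DEFAULT_OFFSET,
) -> np.ndarray:
    """Thin a 165-sample ratio trace to 16 values (every ``stride``-th).

    Default keeps indices 0, 10, ..., 150; taking every 10th value was
    found not to increase the classification error while cutting each
    sensor's block from 165 to 16 numbers.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    if ratios.shape != (COOL_SAMPLES,):
        raise ValueError(
            f"expected a cooling segment of length {COOL_SAMPLES}, "
            f"got shape {ratios.shape}"
        )
    last = offset + (N_RATIOS_PER_SENSOR - 1) * stride
    if offset < 0 or stride < 1 or last >= COOL_SAMPLES:
        raise ValueError(
            f"offset={offset}, stride={stride} does not yield "
            f"{N_RATIOS_PER_SENSOR} indices within 0..{COOL_SAMPLES - 1}"
        )
    return ratios[offset : last + 1 : stride]


def build_feature_vector(
    seg: SegmentedRecord,
    num_period: int = DEFAULT_NUM_PERIOD,
    den_period: int = DEFAULT_DEN_PERIOD,
    stride: int = DEFAULT_STRIDE,
    offset: int = DEFAULT_OFFSET,
) -> FeatureVector:
    """Assemble the 227-value input vector for one segmented record."""
    ratios = ratio_features(seg, num_period=num_period, den_period=den_period)
    blocks = [downsample(ratios[s], stride=stride, offset=offset) for s in range(N_SENSORS)]
    meta = encode_metadata(seg.age, seg.sex, seg.smoking)
    values = np.concatenate(blocks + [np.asarray(meta)])
    return FeatureVector(values=values, label=seg.label, record_id=seg.record_id)


def feature_names(stride: int = DEFAULT_STRIDE, offset: int = DEFAULT_OFFSET) -> List[str]:
    names = [
        f"s{s + 1:02d}_f{f + 1:02d}"
        for s in range(N_SENSORS)
        for f in range(N_RATIOS_PER_SENSOR)
    ]
    return names + ["age", "sex", "smoking"]


class RatioFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: raw records -> (n_subjects, 227) feature matrix.

    Parameters
    ----------
    num_period, den_period : int
        1-based complete-cycle indices of the ratio numerator and
        denominator (defaults 4 and 1).
    stride, offset : int
        Thinning of each 165-sample ratio trace to 16 values.
    min_run : int
        Sync-channel debounce length passed to cycle detection.
    """

    def __init__(
        self,
        num_period: int = DEFAULT_NUM_PERIOD,
        den_period: int = DEFAULT_DEN_PERIOD,
        stride: int = DEFAULT_STRIDE,
        offset: int = DEFAULT_OFFSET,
        min_run: int = 5,
    ):
        self.num_period = num_period
        self.den_period = den_period
        self.stride = stride
        self.offset = offset
        self.min_run = min_run

    def fit(self, X=None, y=None) -> "RatioFeatureExtractor":
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X: Union[Cohort, Iterable[SensorRecord]]) -> np.ndarray:
        vectors = self.extract(X)
        return np.stack([fv.values for fv in vectors]) if vectors else np.empty((0, N_FEATURES))

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def extract(self, X: Union[Cohort, Iterable[SensorRecord]]) -> List[FeatureVector]:
        """Like :meth:`transform` but keeps record ids and labels."""
        records = X.records if isinstance(X, Cohort) else list(X)
        out = []
        for rec in records:
            seg = segment_record(rec, min_run=self.min_run)
            out.append(
                build_feature_vector(
                    seg,
                    num_period=self.num_period,
                    den_period=self.den_period,
                    stride=self.stride,
                    offset=self.offset,
                )
            )
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(feature_names(self.stride, self.offset), dtype=object)


def extract_feature_table(
    cohort: Union[Cohort, Iterable[SensorRecord]],
    num_period: int = DEFAULT_NUM_PERIOD,
    den_period: int = DEFAULT_DEN_PERIOD,
    stride: int = DEFAULT_STRIDE,
    offset: int = DEFAULT_OFFSET,
) -> pd.DataFrame:
    """Feature matrix as a DataFrame: record_id, label, s01_f01..smoking."""
    extractor = RatioFeatureExtractor(
        num_period=num_period, den_period=den_period, stride=stride, offset=offset
    )
    vectors = extractor.extract(cohort)
    frame = pd.DataFrame(
        [fv.values for fv in vectors], columns=feature_names(stride, offset)
    )
    frame.insert(0, "label", [fv.label for fv in vectors])
    frame.insert(0, "record_id", [fv.record_id for fv in vectors])
    return frame


def feature_table_to_vectors(frame: pd.DataFrame) -> List[FeatureVector]:
    """Inverse of :func:`extract_feature_table` (e.g. after a CSV round trip)."""
    cols = [c for c in frame.columns if c not in ("record_id", "label")]
    if len(cols) != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} feature columns, got {len(cols)}")
    return [
        FeatureVector(
            values=row[cols].to_numpy(dtype=np.float64),
            label=int(row["label"]),
            record_id=str(row["record_id"]),
        )
        for _, row in frame.iterrows()
    ]
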
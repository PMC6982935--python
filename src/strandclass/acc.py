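"""Autocross-covariance (ACC) transformation.

Variable-length residue profiles (a P x L matrix per protein) cannot feed a
fixed-input classifier directly.  The ACC transform converts them into
fixed-length vectors by measuring lagged covariance along the sequence:

* AC(i, lg) — autocovariance of property row i at lag lg:
  sum_{j=1..L-lg} (s_ij - sbar_i)(s_i,j+lg - sbar_i) / (L - lg),
  with sbar_i the mean of row i over all L positions;
* CC(i1, i2, lg) — cross-covariance between two distinct property rows at lag
  lg, same normalisation.

Lags run 1..LG.  AC alone yields P * LG values; CC adds P * (P - 1) * LG
values for the ordered pairs of distinct properties.  AC is invariant to
adding a constant to a row and scales quadratically when a row is multiplied
by a constant — both covariance facts the tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import List

import numpy as np

from .types import FeatureBlock, ResidueProfile, StrandclassError

logger = logging.getLogger(__name__)

#: Default maximum lag.
DEFAULT_LG = 5


@dataclass(frozen=True)
class ACCConfig:
    """Configuration of the transform: maximum lag LG and whether the
    cross-covariance (CC) variables are appended to the autocovariances."""

    lg: int = DEFAULT_LG
    include_cc: bool = False

    def __post_init__(self) -> None:
        if self.lg < 1:
            raise StrandclassError(f"maximum lag must be >= 1, got {self.lg}")


def _check_length(profile: ResidueProfile, config: ACCConfig) -> None:
    if profile.length <= config.lg:
        raise StrandclassError(
            f"protein {profile.protein_id!r}: profile length {profile.length} "
            f"<= maximum lag {config.lg}; cannot compute lagged covariances"
        )


def ac(profile: ResidueProfile, config: ACCConfig = ACCConfig()) -> FeatureBlock:
    """Autocovariance features: one value per (property row, lag).

    Output is ordered property-major then lag; labels encode the property
    name and the lag.  Requires L >= LG + 1.
    """
    _check_length(profile, config)
    s = profile.values
    length = profile.length
    means = s.mean(axis=1, keepdims=True)
    centered = s - means
    values: List[float] = []
    labels: List[str] = []
    for i, prop in enumerate(profile.property_names):
        for lag in range(1, config.lg + 1):
            cov = float(
                np.dot(centered[i, : length - lag], centered[i, lag:]) / (length - lag)
            )
            values.append(cov)
            labels.append(f"AC:{prop}:lag{lag}")
    return FeatureBlock(source="AC", labels=labels, values=np.asarray(values))


def cc(profile: ResidueProfile, config: ACCConfig = ACCConfig()) -> FeatureBlock:
    """Cross-covariance features: one value per ordered pair of distinct
    property rows and lag.  Requires at least two property rows."""
    _check_length(profile, config)
    if profile.n_properties < 2:
        raise StrandclassError(
            f"protein {profile.protein_id!r}: cross-covariance needs >= 2 "
            f"properties, got {profile.n_properties}"
        )
    s = profile.values
    length = profile.length
    centered = s - s.mean(axis=1, keepdims=True)
    values: List[float] = []
    labels: List[str] = []
    for i1, p1 in enumerate(profile.property_names):
        for i2, p2 in enumerate(profile.property_names):
            if i1 == i2:
                continue
            for lag in range(1, config.lg + 1):
                cov = float(
                    np.dot(centered[i1, : length - lag], centered[i2, lag:])
                    / (length - lag)
                )
                values.append(cov)
                labels.append(f"CC:{p1}:{p2}:lag{lag}")
    return FeatureBlock(source="CC", labels=labels, values=np.asarray(values))


def acc(profile: ResidueProfile, config: ACCConfig = ACCConfig()) -> FeatureBlock:
    """AC features, plus CC features iff ``config.include_cc``.

    A single-property profile with ``include_cc=True`` degrades to AC-only
    (there are no property pairs); this is logged, not an error.
    """
    ac_block = ac(profile, config)
    if not config.include_cc:
        return ac_block
    if profile.n_properties < 2:
        logger.info(
            "protein %r: include_cc requested but profile has a single "
            "property; emitting AC variables only",
            profile.protein_id,
        )
        return ac_block
    cc_block = cc(profile, config)
    return FeatureBlock(
        source="ACC",
        labels=ac_block.labels + cc_block.labels,
        values=np.concatenate([ac_block.values, cc_block.values]),
    )
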
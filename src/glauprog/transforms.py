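"""Scale conversions between linear and logarithmic sensitivity/thickness scales.

Perimetric sensitivity is reported in decibels of attenuation; the underlying
physical quantity is differential light sensitivity on the reciprocal-Lambert
(1/L) scale, related by ``dB = 10 * log10(1/L)``.  Circumpapillary RNFL
thickness (micrometres) has an analogous logarithmic companion scale,
``LogRNFLT = 10 * log10(thickness_um)``, under which the structure-function
relationship is approximately linear.

Only the two paired conversions (dB <-> 1/L, um <-> LogRNFLT) are meaningful;
the :class:`ScaleConverter` transformer enforces that pairing.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: Valid scale tags and the conversion partners they admit.
SCALE_PAIRS = {
    "dB": "one_over_L",
    "one_over_L": "dB",
    "um": "LogRNFLT",
    "LogRNFLT": "um",
}

#: Thickness floor (um) applied before taking logarithms.  Pathological
#: sectors can thin below 10 um and occasionally reach 0; clamping keeps the
#: log scale finite without meaningfully distorting valid measurements.
DEFAULT_CLAMP_FLOOR_UM = 1.0


def _as_float(v):
    a = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite input to scale conversion")
    return a


def db_to_antilog(v):
    """Convert decibel sensitivity to the linear 1/Lambert scale.

    ``1/L = 10**(dB/10)``; strictly increasing, 0 dB maps to 1.
    """
    return 10.0 ** (_as_float(v) / 10.0)


def antilog_to_db(v):
    """Convert 1/Lambert sensitivity to decibels: ``dB = 10*log10(1/L)``.

    Raises ``ValueError`` for non-positive input (no physical meaning on the
    reciprocal-luminance scale).
    """
    a = _as_float(v)
    if np.any(a <= 0):
        raise ValueError("1/Lambert values must be strictly positive")
    return 10.0 * np.log10(a)


def rnflt_to_log(t, clamp_floor=DEFAULT_CLAMP_FLOOR_UM):
    """Convert RNFL thickness (um) to the logarithmic scale 10*log10(t).

    Values below ``clamp_floor`` (default 1 um) are clamped with a warning so
    that degenerate segmentations cannot produce -inf.  Pass
    ``clamp_floor=None`` to disable clamping, in which case non-positive
    thickness raises ``ValueError``.
    """
    a = _as_float(t)
    if clamp_floor is not None:
        if np.any(a < clamp_floor):
            n = int(np.sum(a < clamp_floor))
            logger.warning(
                "clamped %d thickness value(s) below %.3g um before log transform",
                n, clamp_floor)
        a = np.maximum(a, clamp_floor)
    elif np.any(a <= 0):
        raise ValueError("thickness must be positive when clamping is disabled")
    return 10.0 * np.log10(a)


def log_to_rnflt(v):
    """Inverse of :func:`rnflt_to_log`: ``t = 10**(LogRNFLT/10)`` um."""
    return 10.0 ** (_as_float(v) / 10.0)


_FORWARD = {
    ("dB", "one_over_L"): db_to_antilog,
    ("one_over_L", "dB"): antilog_to_db,
    ("um", "LogRNFLT"): rnflt_to_log,
    ("LogRNFLT", "um"): log_to_rnflt,
}


def convert_scale(values, src: str, dst: str):
    """Convert ``values`` from scale ``src`` to scale ``dst``.

    Only the paired conversions dB<->1/L and um<->LogRNFLT are defined.
    Identity conversions are allowed and return the input as float array.
    """
    if src == dst:
        return _as_float(values)
    key = (src, dst)
    if key not in _FORWARD:
        raise ValueError(f"no conversion from scale {src!r} to {dst!r}")
    return _FORWARD[key](values)


class ScaleConverter(TransformerMixin, BaseEstimator):
    """Stateless transformer converting between a paired pair of scales.

    Parameters
    ----------
    src, dst : str
        Scale tags; must be partners in :data:`SCALE_PAIRS` (or equal).

    The transformer is sklearn-compatible (``fit`` is a no-op) so scale
    changes can sit inside a :class:`sklearn.pipeline.Pipeline`.
    """

    def __init__(self, src: str = "dB", dst: str = "one_over_L"):
        self.src = src
        self.dst = dst

    def fit(self, X, y=None):
        if self.src != self.dst and SCALE_PAIRS.get(self.src) != self.dst:
            raise ValueError(f"scales {self.src!r} and {self.dst!r} are not a convertible pair")
        self.n_features_in_ = np.asarray(X).shape[-1] if np.ndim(X) > 1 else 1
        return self

    def transform(self, X):
        return convert_scale(X, self.src, self.dst)

    def inverse_transform(self, X):
        return convert_scale(X, self.dst, self.src)
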
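"""Evaluation statistics for affinity regression.

MSE, the concordance index (CI) over all ordered pairs with strictly
different true affinities, the QSAR external-validation statistic r^2_m,
and the pKd transform for raw dissociation constants in nM.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "MetricsReport",
    "mse",
    "concordance_index",
    "rm2",
    "pkd_transform",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    ci: float
    rm2: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true, dtype=np.float64).ravel()
    p = np.asarray(y_pred, dtype=np.float64).ravel()
    if y.size == 0:
        raise ValueError("empty input vectors")
    if y.size != p.size:
        raise ValueError(f"length mismatch: {y.size} true vs {p.size} predicted")
    return y, p


def mse(y_true, y_pred) -> float:
    """Mean squared error ``(1/n) sum (yhat_i - y_i)^2``."""
    y, p = _validate_pair(y_true, y_pred)
    return float(np.mean((p - y) ** 2))


def concordance_index(y_true, y_pred) -> float:
    """Concordance index over ordered pairs with different true values.

    For every pair with ``d_x > d_y`` the prediction pair earns credit 1
    if ranked the same way, 0.5 on a prediction tie, and 0 otherwise;
    the total is divided by the number of such pairs.  Pairs with tied
    true values contribute nothing.

    Raises
    ------
    ValueError
        If every true value is tied (no comparable pair exists).
    """
    y, p = _validate_pair(y_true, y_pred)
    greater = y[:, None] > y[None, :]  # ordered pairs (x, y) with d_x > d_y
    z = int(greater.sum())
    if z == 0:
        raise ValueError("concordance index undefined: all true values are tied")
    diff = p[:, None] - p[None, :]
    credit = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float(credit[greater].sum() / z)


def rm2(y_true, y_pred) -> float:
    """r^2_m = r^2 * (1 - sqrt(r^2 - r0^2)).

    ``r^2`` is the squared Pearson correlation (with intercept) between
    true and predicted values; ``r0^2`` is the squared correlation through
    the origin, ``1 - sum(y_i - k yhat_i)^2 / sum(y_i - ybar)^2`` with the
    through-origin slope ``k = sum(y_i yhat_i) / sum(yhat_i^2)``.  The
    radicand is clamped at zero against floating-point negatives, so
    r^2_m never exceeds r^2.
    """
    y, p = _validate_pair(y_true, y_pred)
    if y.size < 3:
        raise ValueError("r^2_m needs at least 3 points")
    if np.var(y) == 0 or np.var(p) == 0:
        raise ValueError("r^2_m undefined for constant inputs")
    r = np.corrcoef(y, p)[0, 1]
    r2 = r * r
    k = float(np.sum(y * p) / np.sum(p * p))
    r02 = 1.0 - float(np.sum((y - k * p) ** 2) / np.sum((y - y.mean()) ** 2))
    return float(r2 * (1.0 - np.sqrt(max(r2 - r02, 0.0))))


def pkd_transform(kd_nM):
    """Convert a dissociation constant in nM to pKd: ``-log10(Kd / 1e9)``."""
    kd = np.asarray(kd_nM, dtype=np.float64)
    if np.any(kd <= 0):
        raise ValueError("Kd must be positive")
    out = -np.log10(kd / 1e9)
    return float(out) if out.ndim == 0 else out


def evaluate_predictions(y_true, y_pred) -> MetricsReport:
    """Bundle MSE, CI and r^2_m into one report."""
    y, p = _validate_pair(y_true, y_pred)
    return MetricsReport(
        mse=mse(y, p),
        ci=concordance_index(y, p),
        rm2=rm2(y, p),
        n=int(y.size),
    )
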
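"""Quantitative optimization of kernel choice and training-sample proportion.

Raising the training proportion buys accuracy but costs training time, and
the trade differs per kernel. The performance factor

    P = (Acc - Acc_min) * (T_ref / T)^n

scores one operating point: ``Acc_min`` is the accuracy the application
requires, ``T`` the mean training time at the operating point, ``T_ref`` the
training time at which the kernel first reaches ``Acc_min`` (interpolated
along the proportion sweep), and ``n`` in (0, 1] weights how much long
training is penalized (larger n = stronger penalty). P is negative exactly
when the accuracy requirement is missed, grows with accuracy at fixed time,
and shrinks as training slows at fixed accuracy. The global peak of P over
(kernel, proportion) is the optimized configuration.

The algebraic form lives in :func:`performance_factor` alone; everything
else depends only on its sign/monotonicity contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import AnalysisError, InputError
from .svm import Dataset, KernelSpec, repeat_evaluate

__all__ = [
    "DEFAULT_PROPORTIONS",
    "PerfConfig",
    "PerfCurve",
    "performance_factor",
    "calibrate_t_ref",
    "sweep_proportions",
    "find_optimum",
    "model_train_time",
]

#: Default training-proportion grid for sweeps.
DEFAULT_PROPORTIONS = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50)

_KERNEL_RANK = {"linear": 0, "poly": 1, "rbf": 2}


@dataclass
class PerfConfig:
    """Performance-factor settings.

    ``acc_min``: required minimum accuracy (fraction); ``n``: training-time
    sensitivity in (0, 1]; ``t_ref``: training time (s) at the minimum
    accuracy, normally filled in per kernel by :func:`calibrate_t_ref`.
    """

    acc_min: float = 0.95
    n: float = 1.0
    t_ref: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.acc_min < 1.0:
            raise InputError(f"acc_min must be in (0, 1), got {self.acc_min}")
        if not 0.0 < self.n <= 1.0:
            raise InputError(f"sensitivity n must be in (0, 1], got {self.n}")
        if self.t_ref is not None and self.t_ref <= 0.0:
            raise InputError("t_ref must be positive")


@dataclass
class PerfCurve:
    """Performance factor versus training proportion for one kernel.

    Infeasible kernels (never reaching ``acc_min`` on the sweep) are carried
    with ``feasible=False`` and ``p=None`` rather than dropped.
    """

    kernel: str
    proportions: np.ndarray
    acc: np.ndarray
    t: np.ndarray
    p: np.ndarray | None
    t_ref: float | None
    feasible: bool
    auc: np.ndarray | None = None


def performance_factor(acc: float, t: float, cfg: PerfConfig) -> float:
    """P = (acc - acc_min) * (t_ref / t)^n for one operating point."""
    if t <= 0.0:
        raise InputError(f"training time must be positive, got {t}")
    if cfg.t_ref is None:
        raise InputError("PerfConfig.t_ref is not set; calibrate it first")
    return float((acc - cfg.acc_min) * (cfg.t_ref / t) ** cfg.n)


def calibrate_t_ref(
    curve_acc: Sequence[float], curve_t: Sequence[float], cfg: PerfConfig
) -> float:
    """Training time at which the sweep first reaches the minimum accuracy.

    Scans the sweep in proportion order for the first point with
    ``acc >= acc_min``; when the previous point was below the standard, the
    time is linearly interpolated in accuracy between the bracketing points.
    """
    acc = np.asarray(curve_acc, dtype=np.float64)
    t = np.asarray(curve_t, dtype=np.float64)
    if acc.shape != t.shape or acc.ndim != 1 or len(acc) == 0:
        raise InputError("accuracy and time curves must be equal-length 1-D")
    hits = np.flatnonzero(acc >= cfg.acc_min)
    if len(hits) == 0:
        raise AnalysisError("kernel infeasible at this standard")
    i = int(hits[0])
    if i == 0 or acc[i] == acc[i - 1]:
        return float(t[i])
    frac = (cfg.acc_min - acc[i - 1]) / (acc[i] - acc[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def model_train_time(n_train: int) -> float:
    """Deterministic training-cost model: quadratic in the training size.

    Used by ``timing="model"`` sweeps so that optimization output is a pure
    function of the seed — wall-clock timing is not reproducible bit-for-bit.
    The absolute scale is arbitrary; only ratios enter the performance factor.
    """
    return (n_train / 100.0) ** 2 + 1e-3


def sweep_proportions(
    ds: Dataset,
    kernels: Sequence[KernelSpec],
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    reps: int = 100,
    cfg: PerfConfig | None = None,
    seed: int = 0,
    timing: str = "wall",
) -> list[PerfCurve]:
    """Evaluate every kernel over the proportion grid and score it with P.

    Per kernel: ``repeat_evaluate`` at every proportion (times averaged over
    the repetitions before P is computed), ``t_ref`` calibrated on the
    resulting curve, then P per proportion. ``timing="model"`` replaces the
    measured mean training times with the deterministic cost model.
    """
    cfg = cfg or PerfConfig()
    props = np.asarray(sorted(proportions), dtype=np.float64)
    if np.any(props <= 0.0) or np.any(props >= 1.0):
        raise InputError("proportions must lie in (0, 1)")
    if timing not in ("wall", "model"):
        raise InputError(f"timing must be 'wall' or 'model', got {timing!r}")
    n_per_class = {
        int(lab): int(np.sum(ds.y == lab)) for lab in sorted(set(ds.y.tolist()))
    }
    curves: list[PerfCurve] = []
    for ki, spec in enumerate(kernels):
        acc = np.zeros(len(props))
        t = np.zeros(len(props))
        auc = np.zeros(len(props))
        for pi, prop in enumerate(props):
            res = repeat_evaluate(ds, spec, float(prop), reps, seed + 1000 * ki)
            acc[pi] = res.accuracy
            auc[pi] = res.auc if res.auc is not None else np.nan
            if timing == "model":
                n_train = sum(
                    int(np.floor(prop * n + 0.5)) for n in n_per_class.values()
                )
                t[pi] = model_train_time(n_train)
            else:
                t[pi] = res.train_time
        try:
            t_ref = calibrate_t_ref(acc, t, cfg)
        except AnalysisError:
            curves.append(
                PerfCurve(spec.kind, props.copy(), acc, t, None, None, False, auc)
            )
            continue
        kcfg = replace(cfg, t_ref=t_ref)
        p = np.array([performance_factor(a, tt, kcfg) for a, tt in zip(acc, t)])
        curves.append(PerfCurve(spec.kind, props.copy(), acc, t, p, t_ref, True, auc))
    return curves


def find_optimum(curves: Sequence[PerfCurve]) -> tuple[str, float, float]:
    """Global argmax of P over all (kernel, proportion) points.

    Ties at the peak break toward the smaller proportion (cheaper training),
    then toward the fixed kernel order linear, poly, rbf. Raises when no
    swept point meets the accuracy standard.
    """
    best_key: tuple[float, float, int] | None = None
    best: tuple[str, float, float] | None = None
    for curve in curves:
        if not curve.feasible or curve.p is None:
            continue
        for prop, p in zip(curve.proportions, curve.p):
            if p < 0.0:
                continue
            key = (-float(p), float(prop), _KERNEL_RANK.get(curve.kernel, 99))
            if best_key is None or key < best_key:
                best_key = key
                best = (curve.kernel, float(prop), float(p))
    if best is None:
        raise AnalysisError("no configuration meets the accuracy standard")
    return best
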
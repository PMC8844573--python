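"""Hertz-model elasticity from AFM approach force curves.

The contact law for a rigid spherical probe of radius R pressed a depth
delta into an elastic half-space of Young's modulus E and Poisson ratio nu
is

    F = 4 * E * sqrt(R) * delta**1.5 / (3 * (1 - nu**2))

Each curve is fitted individually by nonlinear least squares over
(E, contact point, baseline offset); curves then pass three strict quality
gates — rms residual below 25 pN, contact-point deviation below 100 nm, and
fitted E inside [1e2, 1e4] Pa — before being pooled into per-group means.
The contact-point deviation is defined here as the distance between the
least-squares contact point and an independent threshold-crossing estimate
of the contact position.
"""
from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import ForceCurve, GroupSummary, HertzFit, ProbeSpec, sem

__all__ = [
    "hertz_force",
    "estimate_contact_point",
    "fit_hertz",
    "qc_filter",
    "aggregate_elasticity",
    "method_difference",
    "RMS_MAX",
    "CP_DEV_MAX",
    "E_RANGE",
]

# default quality gates (N, m, Pa)
RMS_MAX = 25e-12
CP_DEV_MAX = 100e-9
E_RANGE = (1e2, 1e4)


def hertz_force(
    E: float, probe: ProbeSpec, delta: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Contact force (N) at indentation depth ``delta`` (m).

    Monotone increasing in both ``delta`` and ``E``; zero at zero depth.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth cannot be negative")
    out = (
        4.0
        * E
        * math.sqrt(probe.radius)
        / (3.0 * (1.0 - probe.poisson**2))
        * delta**1.5
    )
    return float(out) if out.ndim == 0 else out


def estimate_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.25,
    k: float = 3.0,
    m: int = 5,
) -> float:
    """Threshold-crossing contact estimate.

    The first ``baseline_fraction`` of the approach samples define the
    pre-contact baseline (mean and sd); the contact point is the position of
    the first sample opening a run of ``m`` consecutive samples above
    ``mean + k * sd``. Invariant to a constant force offset.
    """
    n = curve.position.size
    n_base = max(int(n * baseline_fraction), 5)
    base = curve.force[:n_base]
    mu, sd = float(base.mean()), float(base.std())
    threshold = mu + k * sd
    above = curve.force > threshold
    # first index opening a run of m consecutive supra-threshold samples
    run = 0
    for i in range(n):
        run = run + 1 if above[i] else 0
        if run == m:
            return float(curve.position[i - m + 1])
    raise ValueError("no sustained force rise found: baseline-only curve?")


def _piecewise_model(
    position: np.ndarray, E: float, cp: float, offset: float, probe: ProbeSpec
) -> np.ndarray:
    delta = np.clip(position - cp, 0.0, None)
    return offset + hertz_force(E, probe, delta)


def fit_hertz(
    curve: ForceCurve,
    probe: ProbeSpec,
    contact_estimate: Optional[float] = None,
) -> HertzFit:
    """Least-squares fit of (E, contact point, baseline offset) to one curve.

    The model is piecewise: pure offset before the contact point, offset
    plus the spherical-indenter law beyond it, with indentation
    ``delta = max(position - contact_point, 0)``. The rms residual is taken
    over the full fitted segment. Non-convergence or a baseline-only curve
    yields a rejected fit rather than an exception.
    """
    z, f = curve.position, curve.force
    try:
        cp0 = contact_estimate if contact_estimate is not None else estimate_contact_point(curve)
    except ValueError:
        return HertzFit(
            E=float("nan"),
            contact_point=float("nan"),
            baseline_offset=float("nan"),
            rms_residual=float("inf"),
            contact_point_deviation=float("inf"),
            accepted=False,
            reject_reason="rms",
            metadata=dict(curve.metadata),
        )

    offset0 = float(f[z < cp0].mean()) if np.any(z < cp0) else float(f[:5].mean())
    # closed-form E seed from the deepest point
    delta_max = max(float(z[-1] - cp0), 1e-9)
    f_max = max(float(f[-1] - offset0), 1e-15)
    E0 = 3.0 * (1.0 - probe.poisson**2) * f_max / (4.0 * math.sqrt(probe.radius) * delta_max**1.5)
    E0 = min(max(E0, 1.0), 1e7)

    span = float(z[-1] - z[0])
    f_scale = max(float(np.ptp(f)), 1e-12)

    def residuals(params: np.ndarray) -> np.ndarray:
        E, cp, offset = params
        return _piecewise_model(z, E, cp, offset, probe) - f

    try:
        sol = least_squares(
            residuals,
            x0=[E0, cp0, offset0],
            bounds=([1e-3, z[0], -np.inf], [1e8, z[-1], np.inf]),
            x_scale=[max(E0, 100.0), span, f_scale],
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        converged = sol.success
    except Exception:
        converged = False

    if not converged:
        return HertzFit(
            E=float("nan"),
            contact_point=cp0,
            baseline_offset=offset0,
            rms_residual=float("inf"),
            contact_point_deviation=float("inf"),
            accepted=False,
            reject_reason="rms",
            metadata=dict(curve.metadata),
        )

    E, cp, offset = map(float, sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    cp_dev = abs(cp - cp0)
    return HertzFit(
        E=E,
        contact_point=cp,
        baseline_offset=offset,
        rms_residual=rms,
        contact_point_deviation=cp_dev,
        accepted=False,
        reject_reason="none",
        metadata=dict(curve.metadata),
    )


def qc_filter(
    fits: Sequence[HertzFit],
    rms_max: float = RMS_MAX,
    cp_dev_max: float = CP_DEV_MAX,
    e_range: Tuple[float, float] = E_RANGE,
) -> Tuple[List[HertzFit], Dict[str, int]]:
    """Apply the strict quality gates in order rms -> contact_dev -> e_range.

    Each fit is tagged with the first failing reason; the tally (including
    ``accepted``) always sums to the input size.
    """
    if len(fits) == 0:
        raise ValueError("qc_filter needs at least one fit")
    accepted: List[HertzFit] = []
    tally = {"accepted": 0, "rms": 0, "contact_dev": 0, "e_range": 0}
    for fit in fits:
        if not fit.rms_residual < rms_max:
            fit.accepted, fit.reject_reason = False, "rms"
            tally["rms"] += 1
        elif not fit.contact_point_deviation < cp_dev_max:
            fit.accepted, fit.reject_reason = False, "contact_dev"
            tally["contact_dev"] += 1
        elif not (e_range[0] < fit.E < e_range[1]):
            fit.accepted, fit.reject_reason = False, "e_range"
            tally["e_range"] += 1
        else:
            fit.accepted, fit.reject_reason = True, "none"
            tally["accepted"] += 1
            accepted.append(fit)
    return accepted, tally


def aggregate_elasticity(
    fits: Sequence[HertzFit],
    by: Sequence[str] = ("cell_type",),
    groups: Optional[Iterable[str]] = None,
) -> List[GroupSummary]:
    """Pool accepted fits into per-group mean E, SEM and n.

    ``by`` names metadata keys whose joined values label a group. With an
    explicit ``groups`` list, groups absent from the data are reported with
    n = 0 rather than dropped; a requested key missing from every fit's
    metadata is an error.
    """
    rows = []
    for fit in fits:
        if not fit.accepted:
            continue
        try:
            label = "/".join(str(fit.metadata[k]) for k in by)
        except KeyError as exc:
            raise KeyError(f"metadata key {exc} missing from fit") from exc
        rows.append({"group": label, "E": fit.E})
    df = pd.DataFrame(rows, columns=["group", "E"])
    summaries = []
    seen = set()
    for label, sub in df.groupby("group", sort=True):
        summaries.append(
            GroupSummary(
                group=str(label),
                mean_E=float(sub["E"].mean()),
                sem_E=sem(sub["E"].to_numpy()),
                n=int(len(sub)),
            )
        )
        seen.add(str(label))
    if groups is not None:
        for label in groups:
            if label not in seen:
                summaries.append(
                    GroupSummary(group=label, mean_E=float("nan"), sem_E=float("nan"), n=0)
                )
    return summaries


def method_difference(summary_a: GroupSummary, summary_b: GroupSummary) -> float:
    """Absolute difference of two methods' group means (same cell type), Pa."""
    label_a = summary_a.group.split("/")[0]
    label_b = summary_b.group.split("/")[0]
    if label_a != label_b:
        raise ValueError(
            f"cannot compare different cell types: {summary_a.group!r} vs {summary_b.group!r}"
        )
    return abs(summary_a.mean_E - summary_b.mean_E)
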
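"""Crown volumes: solid of revolution of a fitted profile, geometric
cone, and 3-D convex hull, plus pairwise comparison statistics.

Rotating a profile OR(x) (x = RDINC) about the crown axis gives
V = π · CL · ∫₀¹ OR(x)² dx.  The cone uses the measured LCR as radius
and CL as height; the convex-hull volume is the volume of the 3-D hull
of the crown points.  Methods are compared per tree by absolute error
against a reference and pairwise by two-sided paired t-tests.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad
from scipy.spatial import ConvexHull, QhullError

from .cloud import PointCloud

logger = logging.getLogger(__name__)

QUAD_RTOL = 1e-8


def volume_of_revolution(profile, CL: float, LCR: float | None = None) -> float:
    """π·CL·∫₀¹ OR(x)² dx by adaptive quadrature.

    ``profile`` is a callable OR(rdinc) in metres (any fitted family,
    the reference model, or an arbitrary curve).  ``LCR`` is accepted
    for signature symmetry with the other volume methods; the profile
    callable already embodies it.
    """
    if CL <= 0:
        raise ValueError("CL must be positive")

    def integrand(x):
        v = float(profile(x))
        if not np.isfinite(v):
            raise ValueError(f"profile not finite at RDINC={x}")
        return v * v

    integral, _ = quad(integrand, 0.0, 1.0, epsrel=QUAD_RTOL, epsabs=1e-12,
                       limit=200)
    return float(np.pi * CL * integral)


def cone_volume(LCR: float, CL: float) -> float:
    """V = π·LCR²·CL/3 (cone with the measured LCR and CL)."""
    return float(np.pi * LCR**2 * CL / 3.0)


def hull3d_volume(crown_cloud: PointCloud) -> float:
    """Volume of the 3-D convex hull of the crown points."""
    if len(crown_cloud) < 4:
        raise ValueError("need at least 4 points for a 3-D hull")
    try:
        hull = ConvexHull(crown_cloud.xyz)
    except QhullError as exc:
        raise ValueError(f"degenerate (coplanar) crown cloud: {exc}") from exc
    return float(hull.volume)


def compare_volumes(volumes: pd.DataFrame, reference: str):
    """Per-tree absolute errors against ``reference`` and pairwise paired
    t-tests between every two methods.

    ``volumes`` is long-form (tree_id, method, volume).  Trees missing
    any method are excluded (and logged).  Returns ``(errors, report)``:
    ``errors`` a per-tree table of |V_method − V_reference|, ``report``
    a dict with mean absolute errors and the t-test matrix; a method
    pair with zero-variance differences is reported as "no difference"
    rather than a NaN statistic.
    """
    wide = volumes.pivot(index="tree_id", columns="method", values="volume")
    if reference not in wide.columns:
        raise ValueError(f"reference method {reference!r} not present")
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info("compare_volumes: %d trees missing a method, excluded",
                    n_dropped)
    if len(complete) < 2:
        raise ValueError("need at least 2 trees with all methods present")
    methods = [c for c in complete.columns]
    errors = (
        complete.drop(columns=[reference])
        .sub(complete[reference], axis=0)
        .abs()
    )
    tests = {}
    for m1, m2 in itertools.combinations(methods, 2):
        diff = complete[m1] - complete[m2]
        if np.allclose(diff.std(ddof=1), 0.0):
            tests[f"{m1} vs {m2}"] = {
                "t": None, "p": None, "no_difference": bool(np.allclose(diff, 0)),
                "note": "zero-variance differences",
            }
            continue
        t, p = stats.ttest_rel(complete[m1], complete[m2])
        tests[f"{m1} vs {m2}"] = {"t": float(t), "p": float(p),
                                  "significant_05": bool(p < 0.05)}
    report = {
        "reference": reference,
        "n_trees": int(len(complete)),
        "mean_absolute_error": {m: float(errors[m].mean()) for m in errors.columns},
        "paired_t": tests,
    }
    return errors, report
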
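"""Shared fixtures: simulation truths, small study designs, brute-force
integrator oracles used to cross-check the analytic/exponential solvers."""

from dataclasses import replace

import numpy as np
import pytest

from mrpkpd import default_truth
from mrpkpd.pk_models import clearance_at
from mrpkpd.synthetic_data import StudyDesign


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def quiet_truth(truth):
    return truth.without_variability()


@pytest.fixture(scope="session")
def small_chronic_designs():
    """3-animal-per-group chronic pair for fast estimation tests."""
    return (
        replace(StudyDesign.chronic_study_a(), n_per_group=3),
        replace(StudyDesign.chronic_study_b(), n_per_group=3),
    )


def euler_pk(params, doses, times, nmol_per_mg=1.0, h=0.01):
    """Explicit-Euler reference integrator for the compartmental models.

    Deliberately naive (first-order, fixed step, continuous clearance ramp)
    so it is independent of the production piecewise-analytic propagator.
    """
    t_end = max(times)
    n = int(np.ceil(t_end / h)) + 1
    ad = a1 = a2 = 0.0
    want = {round(float(t), 9): None for t in times}
    boluses = {}
    infusions = []
    for d in doses:
        amt = d.amount * nmol_per_mg
        if d.duration == 0:
            boluses[round(d.time, 9)] = boluses.get(round(d.time, 9), 0.0) + amt
        else:
            infusions.append((d.time, d.time + d.duration, amt / d.duration))
    for i in range(n + 1):
        t = i * h
        key = round(t, 9)
        if key in boluses:
            ad += boluses.pop(key)
        if key in want and want[key] is None:
            want[key] = a1 / params.v1
        cl = clearance_at(params, t)
        k10 = cl / params.v1
        r0 = sum(r for (a, b, r) in infusions if a - 1e-12 <= t < b - 1e-12)
        if params.q > 0:
            k12, k21 = params.q / params.v1, params.q / params.v2
            da1 = params.ka * ad + r0 - (k10 + k12) * a1 + k21 * a2
            da2 = k12 * a1 - k21 * a2
            a2 += h * da2
        else:
            da1 = params.ka * ad + r0 - k10 * a1
        a1 += h * da1
        ad -= h * params.ka * ad
    return np.array([want[round(float(t), 9)] for t in times])


def euler_turnover(drive_fn, t_end, kin, kout, y0, imax=None, ic50=None, h=0.0005):
    """Explicit-Euler reference for the turnover ODEs.

    With imax/ic50 given it integrates the inhibited-input system from y0;
    otherwise ``drive_fn`` is taken as the (already transformed) input rate
    multiplier of ``kin``.
    """
    n = int(np.ceil(t_end / h))
    y = y0
    for i in range(n):
        t = i * h
        c = drive_fn(t)
        if imax is not None:
            rate_in = kin * (1.0 - imax * c / (c + ic50))
        else:
            rate_in = kin * c
        y += h * (rate_in - kout * y)
    return y
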
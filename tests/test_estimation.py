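"""Two-stage estimation: recovery, invariances, bootstrap behavior."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mrpkpd import (
    DoseEvent,
    EstimationError,
    FitResult,
    PkParameters,
    PkStructure,
    ResidualErrorModel,
    bootstrap_ci,
    conc_profile,
    fit_pd_pooled,
    fit_pk_individual,
)
from mrpkpd.pipeline import _PD_INIT_CHRONIC_UACR, stage1_pk_fits
from mrpkpd.synthetic_data import EPL, PF, generate_chronic_study

PROP_ERR = ResidualErrorModel("proportional", 0.15)


def _subject_frame(sid, doses, t_obs, conc, drug="PF-03882845"):
    rows = []
    for d in doses:
        rows.append(dict(ID=sid, TIME=d.time, AMT=d.amount,
                         RATE=(d.amount / d.duration if d.duration else 0.0),
                         DV=np.nan, EVID=1, MDV=1, CMT=1, DOSE=d.amount,
                         GROUP="G", DRUG=drug))
    for t, c in zip(t_obs, conc):
        rows.append(dict(ID=sid, TIME=t, AMT=np.nan, RATE=np.nan, DV=c,
                         EVID=0, MDV=0, CMT=2, DOSE=doses[0].amount,
                         GROUP="G", DRUG=drug))
    return pd.DataFrame(rows).sort_values(["TIME", "EVID"]).reset_index(drop=True)


class TestIndividualPkFit:
    TRUE = PkParameters(ka=1.3, cl_initial=2.1, v1=3.5)
    STRUCTURE = PkStructure(n_compartments=1)

    def _noise_free_data(self, sid=1):
        doses = [DoseEvent(0.0, 10.0), DoseEvent(10.0, 10.0)]
        t = [0.5, 1.0, 2.0, 4.0, 7.0, 11.0, 12.0, 14.0, 17.0, 20.0]
        conc = conc_profile(self.TRUE, doses, t, nmol_per_mg=2000.0).conc
        return _subject_frame(sid, doses, t, conc)

    def test_noise_free_round_trip_recovers_parameters(self):
        # start from population-typical values (as stage 1 does); a far-off
        # start can land on the mirrored absorption/elimination (flip-flop)
        # branch, which reproduces noise-free oral data exactly
        fit = fit_pk_individual(
            self._noise_free_data(), self.STRUCTURE, PROP_ERR,
            init={"ka": 1.5, "cl": 1.8, "v1": 3.0}, nmol_per_mg=2000.0,
        )
        assert fit.converged
        assert fit.params["ka"] == pytest.approx(1.3, rel=1e-3)
        assert fit.params["cl"] == pytest.approx(2.1, rel=1e-3)
        assert fit.params["v1"] == pytest.approx(3.5, rel=1e-3)
        for name in ("ka", "cl", "v1"):
            lo, hi = fit.ci[name]
            assert lo <= fit.params[name] <= hi

    def test_under_determined_data_fails_explicitly(self):
        data = self._noise_free_data()
        thin = pd.concat([
            data[data["EVID"] == 1],
            data[data["EVID"] == 0].head(2),  # 2 observations, 3 parameters
        ])
        with pytest.raises(EstimationError):
            fit_pk_individual(thin, self.STRUCTURE, PROP_ERR,
                              init={"ka": 1.0, "cl": 1.0, "v1": 1.0},
                              nmol_per_mg=2000.0)

    def test_deterministic_given_same_inputs(self):
        kwargs = dict(init={"ka": 1.5, "cl": 1.8, "v1": 3.0}, nmol_per_mg=2000.0)
        f1 = fit_pk_individual(self._noise_free_data(), self.STRUCTURE, PROP_ERR, **kwargs)
        f2 = fit_pk_individual(self._noise_free_data(), self.STRUCTURE, PROP_ERR, **kwargs)
        assert f1.params == f2.params

    def test_truth_beats_perturbed_parameters_on_noise_free_data(self):
        doses = [DoseEvent(0.0, 10.0)]
        t = [1.0, 2.0, 4.0, 7.0]
        obs = conc_profile(self.TRUE, doses, t, nmol_per_mg=2000.0).conc

        def ssr(params):
            pred = conc_profile(params, doses, t, nmol_per_mg=2000.0).conc
            return np.sum(((pred - obs) / obs) ** 2)

        assert ssr(self.TRUE) < ssr(replace(self.TRUE, cl_initial=2.4))
        assert ssr(self.TRUE) < ssr(replace(self.TRUE, ka=1.0))

    def test_replicate_noisy_subjects_recover_clearance(self):
        """20% proportional noise, 200 subjects: median |CL error| < 10%."""
        rng = np.random.default_rng(7)
        doses = [DoseEvent(0.0, 10.0)]
        t = [0.5, 1.0, 2.0, 4.0, 7.0, 10.0, 14.0, 20.0]
        clean = conc_profile(self.TRUE, doses, t, nmol_per_mg=2000.0).conc
        errors = []
        for sid in range(200):
            noisy = np.maximum(clean * (1 + rng.normal(0, 0.2, clean.size)), 1e-6)
            fit = fit_pk_individual(
                _subject_frame(sid, doses, t, noisy), self.STRUCTURE, PROP_ERR,
                init={"ka": 1.0, "cl": 1.5, "v1": 2.0}, nmol_per_mg=2000.0,
            )
            errors.append(abs(fit.params["cl"] - 2.1) / 2.1)
        assert np.median(errors) < 0.10


@pytest.fixture(scope="module")
def small_quiet_pair(quiet_truth, small_chronic_designs):
    """Noise-free 3-per-group chronic pair plus its stage-1 PK fits."""
    a, b = small_chronic_designs
    data = pd.concat(
        [
            generate_chronic_study(a, quiet_truth, 1),
            generate_chronic_study(b, quiet_truth, 2),
        ],
        ignore_index=True,
    )
    pk_map, _ = stage1_pk_fits(data, quiet_truth, "chronic")
    return data, pk_map


class TestPooledPdFit:
    def test_noise_free_round_trip_within_one_percent(self, small_quiet_pair, truth):
        data, pk_map = small_quiet_pair
        fit = fit_pd_pooled(data, pk_map, "uacr", _PD_INIT_CHRONIC_UACR,
                            seed=0, restarts=2)
        assert fit.converged
        assert fit.params["kin"] == pytest.approx(truth.uacr.kin, rel=0.01)
        assert fit.params["kout"] == pytest.approx(truth.uacr.kout, rel=0.01)
        assert fit.params["imax"] == pytest.approx(truth.uacr.imax, rel=0.01)
        assert fit.params[f"ic50_{PF}"] == pytest.approx(10.4, rel=0.01)
        assert fit.params[f"ic50_{EPL}"] == pytest.approx(671.0, rel=0.01)

    def test_swapping_drug_labels_swaps_potencies(self, small_quiet_pair):
        data, pk_map = small_quiet_pair
        swap = {PF: EPL, EPL: PF}
        swapped = data.copy()
        swapped["DRUG"] = swapped["DRUG"].map(lambda d: swap.get(d, d))
        base = fit_pd_pooled(data, pk_map, "uacr", _PD_INIT_CHRONIC_UACR,
                             seed=0, restarts=1)
        flipped = fit_pd_pooled(swapped, pk_map, "uacr", _PD_INIT_CHRONIC_UACR,
                                seed=0, restarts=1)
        assert flipped.params[f"ic50_{PF}"] == pytest.approx(
            base.params[f"ic50_{EPL}"], rel=1e-6
        )
        assert flipped.params[f"ic50_{EPL}"] == pytest.approx(
            base.params[f"ic50_{PF}"], rel=1e-6
        )
        assert flipped.params["kin"] == pytest.approx(base.params["kin"], rel=1e-6)

    def test_estimates_invariant_to_subject_order(self, small_quiet_pair):
        data, pk_map = small_quiet_pair
        shuffled = data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        base = fit_pd_pooled(data, pk_map, "uacr", _PD_INIT_CHRONIC_UACR,
                             seed=0, restarts=1)
        moved = fit_pd_pooled(shuffled, pk_map, "uacr", _PD_INIT_CHRONIC_UACR,
                              seed=0, restarts=1)
        for name, value in base.params.items():
            assert moved.params[name] == pytest.approx(value, rel=1e-6)

    def test_pd_stage_never_modifies_pk_parameters(self, small_quiet_pair):
        data, pk_map = small_quiet_pair
        before = {sid: spk.params for sid, spk in pk_map.items()}
        fit_pd_pooled(data, pk_map, "uacr", _PD_INIT_CHRONIC_UACR, seed=0, restarts=1)
        for sid, params in before.items():
            assert pk_map[sid].params == params  # frozen dataclass equality

    def test_single_drug_data_rejected(self, small_quiet_pair):
        data, pk_map = small_quiet_pair
        only_pf = data[(data["DRUG"].isna()) | (data["DRUG"] == PF)]
        with pytest.raises(EstimationError):
            fit_pd_pooled(only_pf, pk_map, "uacr", _PD_INIT_CHRONIC_UACR,
                          seed=0, restarts=1)

    def test_unknown_endpoint_rejected(self, small_quiet_pair):
        data, pk_map = small_quiet_pair
        with pytest.raises(Exception):
            fit_pd_pooled(data, pk_map, "osteopontin", {}, seed=0)


class TestBootstrap:
    @staticmethod
    def _mean_fit(df: pd.DataFrame) -> FitResult:
        value = float(df.groupby("ID")["DV"].mean().mean())
        return FitResult(params={"mu": value}, objective=0.0, ci={},
                         converged=True, seed=None,
                         n_subjects=df["ID"].nunique(), n_obs=len(df))

    @staticmethod
    def _toy_data(rng, n_subj=12, sd=1.0, mu=5.0):
        rows = []
        for sid in range(n_subj):
            for rep in range(3):
                rows.append(dict(ID=sid, GROUP="g" + str(sid % 2),
                                 DV=mu + sd * rng.normal()))
        return pd.DataFrame(rows)

    def test_same_seed_gives_identical_cis(self):
        data = self._toy_data(np.random.default_rng(0))
        r1 = bootstrap_ci(self._mean_fit, data, n_boot=50, seed=11)
        r2 = bootstrap_ci(self._mean_fit, data, n_boot=50, seed=11)
        assert r1.ci == r2.ci

    def test_zero_variability_gives_zero_width(self):
        data = self._toy_data(np.random.default_rng(0), sd=0.0)
        res = bootstrap_ci(self._mean_fit, data, n_boot=30, seed=1)
        lo, hi = res.ci["mu"]
        assert hi - lo < 1e-12 and lo == pytest.approx(5.0)

    def test_rejects_tiny_n_boot(self):
        data = self._toy_data(np.random.default_rng(0))
        with pytest.raises(Exception):
            bootstrap_ci(self._mean_fit, data, n_boot=1, seed=0)

    def test_coverage_near_nominal(self):
        """95% percentile bootstrap covers the truth in roughly 93-97% of
        replicate experiments (subject-mean estimator, normal noise)."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 150
        for r in range(n_rep):
            data = self._toy_data(rng, n_subj=15, sd=1.0)
            res = bootstrap_ci(self._mean_fit, data, n_boot=199, seed=r)
            lo, hi = res.ci["mu"]
            hits += lo <= 5.0 <= hi
        assert 0.90 <= hits / n_rep <= 0.99
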
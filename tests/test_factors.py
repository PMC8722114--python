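"""Variance-component estimation on crossed random-effects designs."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from hrrforge.factors import (
    ConcordanceDesign,
    DESIGN_FACTORS,
    build_design,
    contribution_report,
    estimate_variance_components,
)
from hrrforge.model import ConfigurationError, FactorLabels


def simulate_design(rng, variances, n_caller=6, n_aligner=4, n_platform=2,
                    n_sample=4, resid=0.25):
    """Balanced crossing with known main-effect variances (raw scale)."""
    levels = {
        "caller": [f"c{i}" for i in range(n_caller)],
        "aligner": [f"a{i}" for i in range(n_aligner)],
        "platform": [f"p{i}" for i in range(n_platform)],
        "sample": [f"s{i}" for i in range(n_sample)],
    }
    eff = {
        f: {lv: rng.normal(0, np.sqrt(variances.get(f, 0.0))) for lv in lvs}
        for f, lvs in levels.items()
    }
    rows = []
    for combo in itertools.product(*(levels[f] for f in DESIGN_FACTORS)):
        y = sum(eff[f][lv] for f, lv in zip(DESIGN_FACTORS, combo))
        y += rng.normal(0, np.sqrt(resid))
        rows.append(dict(zip(DESIGN_FACTORS, combo)) | {"Y": y})
    df = pd.DataFrame(rows)
    return ConcordanceDesign(df, {f: sorted(df[f].unique()) for f in DESIGN_FACTORS})


class TestBuildDesign:
    def test_full_crossing_row_count(self):
        records = [
            (FactorLabels(sample=s, platform=p, aligner=a, caller=c), 0.5)
            for c, a, p, s in itertools.product("ABCDEF", "wxyz", "01", "12345678")
        ]
        design = build_design(records)
        assert design.n_rows == 6 * 4 * 2 * 8 and design.is_complete

    def test_duplicates_averaged(self):
        lb = FactorLabels(sample="s", platform="p", aligner="a", caller="c")
        design = build_design([(lb, 0.4), (lb, 0.6)])
        assert design.n_rows == 1
        assert design.data["Y"].iloc[0] == pytest.approx(0.5)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            build_design([])
        lb = FactorLabels(sample="s", platform="p", aligner="a", caller="c")
        with pytest.raises(ConfigurationError):
            build_design([(lb, 1.5)])


class TestEstimation:
    def test_parameter_recovery_known_components(self):
        """Mean estimates across simulated designs recover the planted variances."""
        rng = np.random.default_rng(77)
        target = {"caller": 4.0, "aligner": 1.0, "platform": 0.25}
        sums = {t: 0.0 for t in list(target) + ["sample", "residual"]}
        n_sim = 60
        for _ in range(n_sim):
            d = estimate_variance_components(simulate_design(rng, target))
            for t in sums:
                sums[t] += d.components[t]
        means = {t: s / n_sim for t, s in sums.items()}
        assert means["caller"] == pytest.approx(4.0, rel=0.25)
        assert means["aligner"] == pytest.approx(1.0, rel=0.35)
        assert means["sample"] < 0.2

    def test_constant_response_all_zero(self):
        rng = np.random.default_rng(1)
        design = simulate_design(rng, {}, resid=0.0)
        design.data["Y"] = 0.42
        d = estimate_variance_components(design)
        assert all(v == 0.0 for v in d.components.values())
        assert all(np.isnan(p) for p in d.proportions.values())

    def test_pure_noise_goes_to_residual(self):
        rng = np.random.default_rng(5)
        comps = []
        for _ in range(30):
            d = estimate_variance_components(simulate_design(rng, {}, resid=1.0))
            comps.append(d.components)
        mean_resid = np.mean([c["residual"] for c in comps])
        assert mean_resid == pytest.approx(1.0, rel=0.15)
        for term in ("caller", "aligner", "platform", "sample"):
            assert np.mean([c[term] for c in comps]) < 0.1

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        design = simulate_design(rng, {"caller": 2.0})
        d1 = estimate_variance_components(design)
        shuffled = ConcordanceDesign(
            design.data.sample(frac=1, random_state=3).reset_index(drop=True),
            design.levels,
        )
        d2 = estimate_variance_components(shuffled)
        for term, v in d1.components.items():
            assert d2.components[term] == pytest.approx(v, abs=1e-9)

    def test_location_invariance(self):
        rng = np.random.default_rng(13)
        design = simulate_design(rng, {"caller": 1.0})
        d1 = estimate_variance_components(design)
        shifted = ConcordanceDesign(design.data.copy(), design.levels)
        shifted.data["Y"] = shifted.data["Y"] + 5.0
        d2 = estimate_variance_components(shifted)
        for term, v in d1.components.items():
            assert d2.components[term] == pytest.approx(v, abs=1e-8)

    def test_incomplete_design_rejected(self):
        rng = np.random.default_rng(2)
        design = simulate_design(rng, {"caller": 1.0})
        broken = ConcordanceDesign(design.data.iloc[:-1], design.levels)
        with pytest.raises(ConfigurationError):
            estimate_variance_components(broken)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(21)
        d = estimate_variance_components(simulate_design(rng, {"caller": 3.0}))
        assert sum(d.proportions.values()) == pytest.approx(1.0)
        assert all(p >= 0 for p in d.proportions.values())


class TestContributionReport:
    def test_ranking_and_tie_break(self):
        rng = np.random.default_rng(31)
        d = estimate_variance_components(
            simulate_design(rng, {"caller": 8.0, "aligner": 0.5})
        )
        report = contribution_report(d)
        assert report["term"].iloc[0] == "caller"
        assert report["proportion"].is_monotonic_decreasing


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestRemlCrossCheck:
    def test_matches_lme4_on_balanced_design(self, tmp_path):
        """Balanced-design ANOVA estimates coincide with lme4 REML."""
        rng = np.random.default_rng(42)
        design = simulate_design(rng, {"caller": 4.0, "aligner": 1.0, "platform": 0.25})
        ours = estimate_variance_components(design)
        csv = tmp_path / "design.csv"
        design.data.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        m <- lmer(Y ~ (1|caller)+(1|aligner)+(1|platform)+(1|sample)+
                      (1|caller:aligner)+(1|caller:platform)+(1|caller:sample)+
                      (1|aligner:platform)+(1|aligner:sample)+(1|platform:sample),
                  data=d,
                  control=lmerControl(check.nobs.vs.nlev='ignore',
                                      check.nobs.vs.nRE='ignore'))
        v <- as.data.frame(VarCorr(m))
        v$grp <- sub('[.][0-9]+$', '', v$grp)
        write.csv(v[, c('grp','vcov')], '{tmp_path / 'reml.csv'}', row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        reml = pd.read_csv(tmp_path / "reml.csv")
        reml["grp"] = reml["grp"].str.replace("Residual", "residual")
        got = dict(zip(reml["grp"], reml["vcov"]))
        for term in ("caller", "aligner", "residual"):
            assert ours.components[term] == pytest.approx(got[term], rel=0.05, abs=0.02)
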
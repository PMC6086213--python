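"""Two-group and mixed-model inference for bouton turnover cohorts.

Two procedures are exposed: the Mann–Whitney U test for two-group
comparisons of per-segment statistics, and a linear mixed-effects model for
the genotype x phase design with random intercepts for mouse and for axon
nested within mouse. Because the real study's raw data are unavailable, the
module also provides operating-characteristic experiments (type-I error,
power, and interaction-coverage simulations on synthetic cohorts) instead
of treating the study's p-values as reproduction targets.

Factor coding fixes the reference levels at wild type and the rest phase;
reported t statistics are coefficient/SE with p-values from the normal
reference, so only |t| and p are comparable across codings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf

from .schedule import TRAIN_REST, StudySchedule

__all__ = [
    "MWResult",
    "LMMResult",
    "mann_whitney",
    "fit_lmm",
    "report_contrasts",
    "ContrastReport",
    "type_i_error",
    "interaction_coverage",
]


@dataclass
class MWResult:
    u_statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # exact | normal_approx
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.u_statistic <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")


def mann_whitney(sample_a, sample_b, exact_max_n: int = 20) -> MWResult:
    """Two-sided Mann–Whitney U test with midrank tie handling.

    Uses the exact null distribution when the pooled sample is small
    (n1 + n2 <= ``exact_max_n``) and tie-free, otherwise the normal
    approximation with tie and continuity corrections. If every value in
    both samples is identical the comparison is degenerate and p = 1.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return MWResult(len(a) * len(b) / 2.0, len(a), len(b), 1.0, "normal_approx", True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= exact_max_n and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal_approx"
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(min(res.pvalue, 1.0))
    return MWResult(float(res.statistic), len(a), len(b), p, method)


@dataclass
class LMMResult:
    fixed_effects: pd.DataFrame  # coef, se, t, p per term
    variance_components: dict[str, float]  # mouse, axon, residual
    n_obs: int
    n_mice: int
    n_axons: int
    converged: bool
    boundary: bool  # a variance component collapsed to ~0
    method: str = "REML, random intercepts mouse + axon-in-mouse, normal-reference p"

    def term(self, name: str) -> pd.Series:
        hits = [t for t in self.fixed_effects.index if name in t]
        if len(hits) != 1:
            raise KeyError(f"term {name!r} matches {hits}")
        return self.fixed_effects.loc[hits[0]]

    def summary(self) -> str:
        lines = [self.method]
        lines.append(
            f"n_obs={self.n_obs} n_mice={self.n_mice} n_axons={self.n_axons} "
            f"converged={self.converged} boundary={self.boundary}"
        )
        lines.append(self.fixed_effects.round(4).to_string())
        vc = ", ".join(f"{k}={v:.3g}" for k, v in self.variance_components.items())
        lines.append(f"variance components: {vc}")
        return "\n".join(lines)


def fit_lmm(
    table: pd.DataFrame,
    response: str = "value",
    genotype_col: str = "genotype",
    phase_col: str = "phase",
    mouse_col: str = "mouse_id",
    axon_col: str = "segment_id",
    reference: tuple[str, str] = ("WT", "rest"),
    include_random: bool = True,
) -> LMMResult:
    """Genotype x phase mixed model on a long per-segment-per-phase table.

    Random intercepts for mouse and for axon nested in mouse, REML
    estimation, fixed-effect p-values from the normal reference. With
    ``include_random=False`` the same mean structure is fitted by ordinary
    least squares (the limit where both variance components are zero).
    """
    df = table.dropna(subset=[response]).copy()
    if df[mouse_col].nunique() < 2:
        raise ValueError("need at least two mice")
    gref, pref = reference
    formula = (
        f"{response} ~ C({genotype_col}, Treatment('{gref}')) "
        f"* C({phase_col}, Treatment('{pref}'))"
    )
    n_mice = df[mouse_col].nunique()
    n_axons = df[axon_col].nunique()

    def _fe(params, bse) -> pd.DataFrame:
        fe = pd.DataFrame({"coef": params, "se": bse})
        fe["t"] = fe["coef"] / fe["se"].replace(0.0, np.nan)
        fe["p"] = 2.0 * sps.norm.sf(np.abs(fe["t"]))
        return fe

    if np.ptp(df[response].to_numpy(float)) == 0:
        # constant response: intercept only, all variances zero
        ols = smf.ols(formula, df).fit()
        fe = _fe(ols.params, ols.bse.where(ols.bse > 0, np.nan))
        fe.loc[fe.index != "Intercept", ["t", "p"]] = np.nan
        vc = {"mouse": 0.0, "axon": 0.0, "residual": 0.0}
        return LMMResult(fe, vc, len(df), n_mice, n_axons, True, True)

    if not include_random:
        ols = smf.ols(formula, df).fit()
        fe = _fe(ols.params, ols.bse)
        vc = {"mouse": 0.0, "axon": 0.0, "residual": float(ols.mse_resid)}
        return LMMResult(fe, vc, len(df), n_mice, n_axons, True, True)

    model = smf.mixedlm(
        formula,
        df,
        groups=df[mouse_col],
        re_formula="1",
        vc_formula={"axon": f"0 + C({axon_col})"},
    )
    # Powell handles the variance-component boundary (sigma^2 -> 0) that
    # gradient methods stall on; fall back to L-BFGS if it ever fails
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method="powell")
        if not result.converged:
            result = model.fit(reml=True, method="lbfgs")
    fe_names = [t for t in result.params.index if t in result.fe_params.index]
    fe = _fe(result.params[fe_names], result.bse[fe_names])
    resid_var = float(result.scale)
    mouse_var = float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0
    axon_var = float(result.vcomp[0]) if len(result.vcomp) else 0.0
    vc = {"mouse": mouse_var, "axon": axon_var, "residual": resid_var}
    boundary = bool(min(mouse_var, axon_var) < 1e-8 * max(resid_var, 1e-12))
    return LMMResult(
        fe, vc, len(df), n_mice, n_axons, bool(result.converged), boundary
    )


# ---------------------------------------------------------------------------
# the comparison battery


def phase_long_table(per_segment: pd.DataFrame, schedule: StudySchedule, statistic: str) -> pd.DataFrame:
    """Long per-segment-per-phase table for a phase-structured statistic.

    ``statistic`` is one of elimination, formation, survival; survival maps
    to day-0→4 survival for the training phase and to the rest-phase
    maintenance of day-4 survivors for the rest phase.
    """
    days = schedule.imaging_days
    mapping = {}
    for _a, _b, name in schedule.phases():
        if statistic == "survival":
            col = f"survival_d{days[1]}" if name == schedule.phase_labels[0] else "maintenance_rest_preexisting"
        else:
            col = f"{statistic}_{name}"
        mapping[name] = col
    rows = []
    for name, col in mapping.items():
        if col not in per_segment.columns:
            continue
        sub = per_segment[["segment_id", "mouse_id", "genotype", col]].rename(
            columns={col: "value"}
        )
        sub["phase"] = name
        rows.append(sub)
    return pd.concat(rows, ignore_index=True).dropna(subset=["value"])


@dataclass
class ContrastReport:
    mann_whitney: pd.DataFrame
    lmm: dict[str, LMMResult]
    notices: list[str] = field(default_factory=list)

    def to_markdown(self) -> str:
        out = ["# Group comparison battery", ""]
        if self.notices:
            out += ["## Notices", *[f"- {n}" for n in self.notices], ""]
        out += ["## Mann–Whitney U contrasts", "", self.mann_whitney.round(4).to_markdown(index=False), ""]
        out += ["## Linear mixed-effects models (genotype x phase)", ""]
        out.append(
            "_Random effects: mouse, and axon nested in mouse (nesting assumed; "
            "the alternative crossed structure is not identifiable here)._"
        )
        for stat, res in self.lmm.items():
            out += ["", f"### {stat}", "```", res.summary(), "```"]
        return "\n".join(out)

    def to_dict(self) -> dict:
        return {
            "mann_whitney": self.mann_whitney.to_dict(orient="records"),
            "lmm": {
                stat: {
                    "fixed_effects": res.fixed_effects.round(6).reset_index().rename(
                        columns={"index": "term"}
                    ).to_dict(orient="records"),
                    "variance_components": res.variance_components,
                    "n_obs": res.n_obs,
                    "n_mice": res.n_mice,
                    "n_axons": res.n_axons,
                    "converged": res.converged,
                    "boundary": res.boundary,
                }
                for stat, res in self.lmm.items()
            },
            "notices": self.notices,
        }


def report_contrasts(
    per_segment: pd.DataFrame, schedule: StudySchedule = TRAIN_REST
) -> ContrastReport:
    """Run the full comparison battery on a per-segment statistics table.

    Mann–Whitney for training-vs-rest within genotype and genotype-vs-
    genotype within phase (elimination and formation fractions, plus
    stabilization and the rest-phase old-vs-new maintenance contrast), and
    the mixed model for elimination, formation, and survival. With a single
    genotype the between-genotype contrasts are skipped with a notice.
    """
    genotypes = sorted(per_segment["genotype"].unique())
    notices = []
    mw_rows = []

    def _mw(label: str, a: np.ndarray, b: np.ndarray) -> None:
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            notices.append(f"contrast {label!r} skipped: empty cell")
            return
        r = mann_whitney(a, b)
        mw_rows.append(
            {
                "contrast": label,
                "U": r.u_statistic,
                "n1": r.n1,
                "n2": r.n2,
                "p": r.p_two_sided,
                "method": r.method,
                "degenerate": r.degenerate,
            }
        )

    phases = [name for _a, _b, name in schedule.phases()]
    for g in genotypes:
        sub = per_segment[per_segment["genotype"] == g]
        if len(phases) >= 2:
            for stat in ("elimination", "formation"):
                _mw(
                    f"{g}: {stat} {phases[0]} vs {phases[1]}",
                    sub[f"{stat}_{phases[0]}"].to_numpy(float),
                    sub[f"{stat}_{phases[1]}"].to_numpy(float),
                )
        if "maintenance_rest_preexisting" in sub.columns:
            _mw(
                f"{g}: rest maintenance, pre-existing vs training-formed",
                sub["maintenance_rest_preexisting"].to_numpy(float),
                sub["stabilization_new"].to_numpy(float),
            )

    if len(genotypes) >= 2:
        g1, g2 = genotypes[0], genotypes[1]
        a = per_segment[per_segment["genotype"] == g1]
        b = per_segment[per_segment["genotype"] == g2]
        for stat in ("elimination", "formation"):
            for ph in phases:
                _mw(
                    f"{g1} vs {g2}: {stat} during {ph}",
                    a[f"{stat}_{ph}"].to_numpy(float),
                    b[f"{stat}_{ph}"].to_numpy(float),
                )
        for col in ("density_alpha", "density_beta", "stabilization_new"):
            if col in per_segment.columns:
                _mw(f"{g1} vs {g2}: {col}", a[col].to_numpy(float), b[col].to_numpy(float))
    else:
        notices.append("single-genotype input: between-genotype contrasts skipped")

    lmm_results: dict[str, LMMResult] = {}
    if len(genotypes) >= 2 and len(phases) >= 2:
        ref_geno = "WT" if "WT" in genotypes else genotypes[0]
        for stat in ("elimination", "formation", "survival"):
            long = phase_long_table(per_segment, schedule, stat)
            try:
                lmm_results[stat] = fit_lmm(
                    long, reference=(ref_geno, phases[-1])
                )
            except ValueError as err:
                notices.append(f"mixed model for {stat} skipped: {err}")
    else:
        notices.append("mixed models need two genotypes and two phases; skipped")

    return ContrastReport(pd.DataFrame(mw_rows), lmm_results, notices)


# ---------------------------------------------------------------------------
# operating-characteristic experiments (synthetic cohorts)


def _simulated_long(preset, schedule: StudySchedule, seed: int, statistic: str,
                    n_segments: int, n_mice: int, genotype: str) -> pd.DataFrame:
    from . import synthcohort, turnoverstats

    segs = synthcohort.sample_cohort(preset, schedule, seed, n_segments=n_segments, n_mice=n_mice)
    table = turnoverstats.segment_statistics(
        synthcohort.lineage_table(segs, schedule), synthcohort.segments_frame(segs), schedule
    )
    table = table.assign(
        genotype=genotype,
        mouse_id=genotype + "_" + table["mouse_id"].astype(str),
        segment_id=genotype + "_" + table["segment_id"].astype(str),
    )
    return table


def type_i_error(
    preset,
    n_reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    statistic: str = "elimination",
    design: tuple[tuple[int, int], tuple[int, int]] = ((58, 6), (54, 7)),
    schedule: StudySchedule = TRAIN_REST,
) -> dict:
    """Interaction-term rejection rate when both 'genotypes' share one preset.

    Simulates the two cohorts from the same latent parameters (so the true
    genotype and genotype x phase effects are exactly zero), fits the mixed
    model, and reports the fraction of replicates with interaction p < alpha.
    """
    ss = np.random.SeedSequence(seed)
    rejections = 0
    used = 0
    for child in ss.spawn(n_reps):
        s1, s2 = child.generate_state(2) >> 1  # keep below 2**31
        a = _simulated_long(preset, schedule, int(s1), statistic, *design[0], "G1")
        b = _simulated_long(preset, schedule, int(s2), statistic, *design[1], "G2")
        long = phase_long_table(pd.concat([a, b], ignore_index=True), schedule, statistic)
        res = fit_lmm(long, reference=("G1", schedule.phase_labels[-1]))
        if not res.converged:
            continue
        used += 1
        term = [t for t in res.fixed_effects.index if ":" in t][0]
        if res.fixed_effects.loc[term, "p"] < alpha:
            rejections += 1
    return {"rejection_rate": rejections / used, "n_used": used, "alpha": alpha}


def interaction_coverage(
    preset_a,
    preset_b,
    n_reps: int = 200,
    seed: int = 0,
    statistic: str = "elimination",
    design: tuple[tuple[int, int], tuple[int, int]] = ((58, 6), (54, 7)),
    schedule: StudySchedule = TRAIN_REST,
    reference_segments: int = 5000,
) -> dict:
    """95% CI coverage of the genotype x phase interaction at study scale.

    The true interaction is taken as the large-sample contrast of cohort
    means computed from one big reference simulation per preset.
    """
    ss = np.random.SeedSequence(seed)
    ref_seeds = ss.spawn(1)[0].generate_state(2) >> 1
    phases = [name for _a, _b, name in schedule.phases()]

    def _cohort_mean(preset, seed_, genotype):
        t = _simulated_long(preset, schedule, int(seed_), statistic, reference_segments, preset.n_mice, genotype)
        long = phase_long_table(t, schedule, statistic)
        return long.groupby("phase")["value"].mean()

    ma = _cohort_mean(preset_a, ref_seeds[0], "A")
    mb = _cohort_mean(preset_b, ref_seeds[1], "B")
    # coding: reference genotype A, reference phase = last; interaction is
    # (B - A) difference of (phase0 - last-phase) contrasts
    true_effect = (mb[phases[0]] - mb[phases[-1]]) - (ma[phases[0]] - ma[phases[-1]])

    covered = 0
    used = 0
    for child in ss.spawn(n_reps + 1)[1:]:
        s1, s2 = child.generate_state(2) >> 1
        a = _simulated_long(preset_a, schedule, int(s1), statistic, *design[0], "A")
        b = _simulated_long(preset_b, schedule, int(s2), statistic, *design[1], "B")
        long = phase_long_table(pd.concat([a, b], ignore_index=True), schedule, statistic)
        res = fit_lmm(long, reference=("A", phases[-1]))
        if not res.converged:
            continue
        used += 1
        term = [t for t in res.fixed_effects.index if ":" in t][0]
        coef = res.fixed_effects.loc[term, "coef"]
        se = res.fixed_effects.loc[term, "se"]
        if abs(coef - true_effect) <= 1.959964 * se:
            covered += 1
    return {"coverage": covered / used, "n_used": used, "true_effect": float(true_effect)}
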
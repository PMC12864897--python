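"""Before/after quality-of-care indicators and adjusted effect estimates.

Three analyses mirror the program-evaluation design:

* per cohort-year indicator tables — sepsis ICD-coding rate, flagged-stay
  rate, and mortality (in-hospital / 30-day / 90-day) among flagged and
  unflagged stays;
* covariate-adjusted odds ratios — logistic regression of a binary outcome
  on admission year (continuous), sex, age and Charlson comorbidity index;
  the reported OR is the exponentiated year coefficient with its Wald 95%
  interval;
* time-to-antibiotics — 1:1 propensity-matched (age, sex, Charlson; logit
  caliper) comparison of pathway vs non-pathway stays, chi-squared test of
  antibiotics within 1 h (or 3 h) of onset.

Cohorts follow the deployment geography: stays *limited to* program wards
(every segment in a program ward group), stays *including* program wards
(at least one segment), and control stays (control wards only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .clinical_scores import charlson_index
from .registry_io import Registry

__all__ = [
    "assign_cohort",
    "stay_cohorts",
    "cohort_indicators",
    "adjusted_odds_ratio",
    "ORResult",
    "tta_matched_comparison",
    "TTAResult",
    "ImpactReport",
    "build_impact_report",
    "stay_covariates",
]

COHORTS = ("stays_including_slhs", "stays_limited_to_slhs", "control", "other")


def assign_cohort(
    ward_groups,
    slhs_groups=("MED", "GIS", "EMD"),
    control_groups=("CONTROL",),
) -> list[str]:
    """Cohort names of one stay from its segment ward groups.

    A stay can be both *including* and *limited to* program wards (limited
    is a subset of including); control requires control wards only. Stays
    in none of the three rules get the residual name ``other``.
    """
    groups = list(ward_groups)
    if not groups:
        raise ValueError("stay has no ward segments")
    in_slhs = [g in slhs_groups for g in groups]
    out = []
    if any(in_slhs):
        out.append("stays_including_slhs")
        if all(in_slhs):
            out.append("stays_limited_to_slhs")
    elif all(g in control_groups for g in groups):
        out.append("control")
    else:
        out.append("other")
    return out


def stay_cohorts(registry: Registry, slhs_groups=("MED", "GIS", "EMD"),
                 control_groups=("CONTROL",)) -> pd.DataFrame:
    """(stay_id, cohort) rows; a stay may appear in two program cohorts."""
    seg = registry.ward_segments.groupby("stay_id")["ward_group"].agg(list)
    rows = []
    for sid, groups in seg.items():
        for cohort in assign_cohort(groups, slhs_groups, control_groups):
            rows.append((sid, cohort))
    return pd.DataFrame(rows, columns=["stay_id", "cohort"])


def stay_covariates(registry: Registry) -> pd.DataFrame:
    """Stay-level covariate table: year, sex, age, Charlson, outcomes."""
    stays = registry.stays.merge(registry.patients, on="patient_id", how="left")
    codes = registry.icd_codes.groupby("stay_id")["code"].agg(list)
    charlson = [
        charlson_index(codes.get(sid, []))
        for sid in stays["stay_id"]
    ]
    admit = stays["admit_ts"]
    death = stays["death_ts"]
    since_admit_d = (death - admit).dt.total_seconds() / 86400.0
    return pd.DataFrame(
        {
            "stay_id": stays["stay_id"],
            "year": admit.dt.year,
            "sex_male": (stays["sex"] == "M").astype(float),
            "age": (admit.dt.year - stays["birth_year"]).astype(float),
            "charlson": charlson,
            "in_hospital_death": stays["in_hospital_death"].astype(bool),
            "death_30d": (since_admit_d <= 30).fillna(False),
            "death_90d": (since_admit_d <= 90).fillna(False),
        }
    )


def _code_matches(code: str, prefixes) -> bool:
    c = code.replace(".", "").upper()
    return any(c.startswith(p.replace(".", "").upper()) for p in prefixes)


def sepsis_coded_stays(registry: Registry, icd_prefixes) -> set[str]:
    codes = registry.icd_codes
    hit = codes.loc[[_code_matches(c, icd_prefixes) for c in codes["code"]]]
    return set(hit["stay_id"])


def cohort_indicators(
    registry: Registry,
    predictions: pd.DataFrame,
    icd_prefixes=("A40", "A41", "R65.2", "R57.2"),
    slhs_groups=("MED", "GIS", "EMD"),
    control_groups=("CONTROL",),
) -> pd.DataFrame:
    """Per (cohort, year) indicator table.

    Percentages of stays with a sepsis ICD code and with a positive model
    flag; mortality among flagged and among unflagged stays. Rates with an
    empty denominator are NaN (undefined), never 0.
    """
    cov = stay_covariates(registry)
    cohorts = stay_cohorts(registry, slhs_groups, control_groups)
    coded = sepsis_coded_stays(registry, icd_prefixes)
    pred = predictions.set_index("stay_id")

    df = cov.merge(cohorts, on="stay_id")
    df["coded"] = df["stay_id"].isin(coded)
    df["flagged"] = df["stay_id"].map(pred["flag"]).fillna(False).astype(bool)

    rows = []
    for (cohort, year), grp in df.groupby(["cohort", "year"]):
        n = len(grp)
        flagged = grp.loc[grp["flagged"]]
        unflagged = grp.loc[~grp["flagged"]]

        def rate(sub, col):
            return float(sub[col].mean() * 100) if len(sub) else float("nan")

        rows.append(
            {
                "cohort": cohort,
                "year": int(year),
                "n_stays": n,
                "pct_sepsis_coded": rate(grp, "coded"),
                "pct_flagged": rate(grp, "flagged"),
                "n_flagged": int(len(flagged)),
                "pct_inhosp_mortality_flagged": rate(flagged, "in_hospital_death"),
                "pct_mortality_30d_flagged": rate(flagged, "death_30d"),
                "pct_mortality_90d_flagged": rate(flagged, "death_90d"),
                "pct_inhosp_mortality_unflagged": rate(unflagged, "in_hospital_death"),
                "pct_mortality_30d_unflagged": rate(unflagged, "death_30d"),
                "pct_mortality_90d_unflagged": rate(unflagged, "death_90d"),
            }
        )
    return pd.DataFrame(rows).sort_values(["cohort", "year"]).reset_index(drop=True)


@dataclass
class ORResult:
    outcome: str
    covariates: tuple[str, ...]
    odds_ratio: float            # per unit year
    ci_low: float
    ci_high: float
    n: int
    converged: bool
    separation: bool = False

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "covariates": list(self.covariates),
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "converged": self.converged,
            "separation": self.separation,
        }


def adjusted_odds_ratio(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("year", "sex_male", "age", "charlson"),
    year_term: str = "year",
) -> ORResult:
    """Maximum-likelihood logistic fit; OR = exp(year coefficient).

    Year enters as a single continuous covariate so the OR reads as the
    per-year change in odds. Degenerate outcomes raise; non-convergence and
    (quasi-)separation are flagged in the result, never silently dropped.
    """
    y = table[outcome].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError(f"degenerate outcome {outcome!r}: all values identical")
    X = table.loc[:, list(covariates)].astype(float).copy()
    if year_term in X.columns:
        X[year_term] = X[year_term] - X[year_term].min()
    X = sm.add_constant(X, has_constant="add")

    separation = False
    converged = True
    import warnings

    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            params = fit.params
            bse = fit.bse
        except (np.linalg.LinAlgError,
                sm.tools.sm_exceptions.PerfectSeparationError):
            raise ValueError("perfect separation: logistic fit impossible")
        if not np.isfinite(bse[year_term]) or bse[year_term] > 1e3:
            separation = True

        beta = float(params[year_term])
        se = float(bse[year_term])
        z = stats.norm.ppf(0.975)
        return ORResult(
            outcome=outcome,
            covariates=covariates,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            n=len(y),
            converged=converged,
            separation=separation,
        )


@dataclass
class TTAResult:
    threshold_hours: float
    n_pairs: int
    contingency: np.ndarray       # rows: pathway/control, cols: timely/late
    chi2: float
    p_value: float
    pct_timely_pathway: float
    pct_timely_control: float

    def to_dict(self) -> dict:
        return {
            "threshold_hours": self.threshold_hours,
            "n_pairs": self.n_pairs,
            "contingency": self.contingency.tolist(),
            "chi2": self.chi2,
            "p_value": self.p_value,
            "pct_timely_pathway": self.pct_timely_pathway,
            "pct_timely_control": self.pct_timely_control,
        }


def _propensity_match(
    covs: pd.DataFrame,
    treated: np.ndarray,
    caliper_sd: float,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """1:1 nearest-neighbour matching on the propensity logit, no replacement."""
    X = sm.add_constant(covs.astype(float), has_constant="add")
    try:
        fit = sm.Logit(treated.astype(float), X).fit(disp=0, maxiter=200)
        logit = np.asarray(X @ fit.params)
    except Exception:
        # propensity model degenerate (e.g. identical covariates): match on 0
        logit = np.zeros(len(covs))
    caliper = caliper_sd * (logit.std() if logit.std() > 0 else 1.0)

    t_idx = np.nonzero(treated)[0]
    c_idx = list(np.nonzero(~treated)[0])
    order = rng.permutation(len(t_idx))
    pairs = []
    for i in t_idx[order]:
        if not c_idx:
            break
        dists = np.abs(logit[c_idx] - logit[i])
        j = int(np.argmin(dists))
        if dists[j] <= caliper:
            pairs.append((int(i), int(c_idx[j])))
            c_idx.pop(j)
    return pairs


def tta_matched_comparison(
    pathway: pd.DataFrame,
    control: pd.DataFrame,
    threshold_hours: float = 1.0,
    caliper_sd: float = 0.2,
    seed: int = 0,
) -> TTAResult:
    """Propensity-matched chi-squared test of timely antibiotics.

    Inputs carry one row per stay with ``age``, ``sex_male``, ``charlson``
    and ``delay_hours`` (first antibiotic after onset; values <= 0, i.e.
    administration at or before onset, count as timely). Matching is 1:1
    nearest neighbour on the logit propensity from (age, sex, Charlson)
    with a ``caliper_sd`` x SD(logit) caliper, without replacement, in
    seeded order.
    """
    cols = ["age", "sex_male", "charlson"]
    all_df = pd.concat(
        [pathway.assign(_t=1), control.assign(_t=0)], ignore_index=True
    )
    treated = all_df["_t"].to_numpy(bool)
    rng = np.random.default_rng(seed)
    pairs = _propensity_match(all_df[cols], treated, caliper_sd, rng)
    if not pairs:
        raise ValueError("no matchable pairs within the caliper")

    pi = [p for p, _ in pairs]
    ci = [c for _, c in pairs]
    timely_p = (all_df["delay_hours"].iloc[pi] <= threshold_hours).to_numpy()
    timely_c = (all_df["delay_hours"].iloc[ci] <= threshold_hours).to_numpy()
    table = np.array(
        [
            [int(timely_p.sum()), int((~timely_p).sum())],
            [int(timely_c.sum()), int((~timely_c).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table)
    return TTAResult(
        threshold_hours=threshold_hours,
        n_pairs=len(pairs),
        contingency=table,
        chi2=float(chi2),
        p_value=float(p),
        pct_timely_pathway=float(timely_p.mean() * 100),
        pct_timely_control=float(timely_c.mean() * 100),
    )


# ---------------------------------------------------------------------------
# assembled impact report


@dataclass
class ImpactReport:
    indicators: pd.DataFrame
    odds_ratios: list = field(default_factory=list)       # ORResult
    tta: list = field(default_factory=list)               # TTAResult

    def to_dict(self) -> dict:
        return {
            "indicators": self.indicators.to_dict(orient="records"),
            "odds_ratios": [o.to_dict() for o in self.odds_ratios],
            "tta": [t.to_dict() for t in self.tta],
        }


def _first_antibiotic_delays(registry: Registry) -> pd.DataFrame:
    """Per event-bearing infected stay: delay (h) from onset to antibiotics."""
    ev = registry.events
    inf = ev.loc[ev["infection"]].sort_values("t0").groupby("stay_id").first()
    meds = registry.medications
    ab = meds.loc[meds["drug_class"] == "antibiotic"]
    rows = []
    for sid, e in inf.iterrows():
        doses = ab.loc[(ab["stay_id"] == sid) & (ab["admin_ts"] >= e["t0"])]
        if not len(doses):
            continue  # censored: never received antibiotics after onset
        delay = (doses["admin_ts"].min() - e["t0"]).total_seconds() / 3600.0
        rows.append((sid, e["source"], max(delay, 0.0)))
    return pd.DataFrame(rows, columns=["stay_id", "source", "delay_hours"])


def build_impact_report(
    registry: Registry,
    predictions: pd.DataFrame,
    icd_prefixes=("A40", "A41", "R65.2", "R57.2"),
    slhs_groups=("MED", "GIS", "EMD"),
    control_groups=("CONTROL",),
    seed: int = 0,
) -> ImpactReport:
    """Indicators, per-cohort year ORs, and matched time-to-antibiotics."""
    indicators = cohort_indicators(
        registry, predictions, icd_prefixes, slhs_groups, control_groups
    )
    cov = stay_covariates(registry)
    cohorts = stay_cohorts(registry, slhs_groups, control_groups)
    coded = sepsis_coded_stays(registry, icd_prefixes)
    pred = predictions.set_index("stay_id")
    cov["coded"] = cov["stay_id"].isin(coded)
    cov["flagged"] = cov["stay_id"].map(pred["flag"]).fillna(False).astype(bool)

    ors = []
    for cohort in ("stays_including_slhs", "stays_limited_to_slhs", "control"):
        ids = set(cohorts.loc[cohorts["cohort"] == cohort, "stay_id"])
        sub = cov.loc[cov["stay_id"].isin(ids)]
        if not len(sub):
            continue
        for outcome in ("coded", "flagged"):
            try:
                o = adjusted_odds_ratio(sub, outcome)
                o.outcome = f"{cohort}:{outcome}"
                ors.append(o)
            except ValueError:
                pass
        flagged = sub.loc[sub["flagged"]]
        for outcome in ("in_hospital_death", "death_90d"):
            try:
                o = adjusted_odds_ratio(flagged, outcome)
                o.outcome = f"{cohort}:{outcome}_flagged"
                ors.append(o)
            except ValueError:
                pass

    tta_results = []
    delays = _first_antibiotic_delays(registry)
    if len(delays):
        d = delays.merge(cov, on="stay_id")
        pathway = d.loc[d["source"] == "orderset"]
        ctrl = d.loc[d["source"] == "id_consult"]
        if len(pathway) and len(ctrl):
            for thr in (1.0, 3.0):
                try:
                    tta_results.append(
                        tta_matched_comparison(pathway, ctrl, thr, seed=seed)
                    )
                except ValueError:
                    pass
    return ImpactReport(indicators=indicators, odds_ratios=ors, tta=tta_results)
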
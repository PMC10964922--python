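"""Looking-time preprocessing, nested mixed models, and BIC null evidence.

The confirmatory model regresses log looking time (natural log, seconds) on
a nested sum-contrast fixed-effect structure — an intercept, a language
effect, and, within each language group, phonotactics, pronunciation,
block, phonotactics × pronunciation, and phonotactics × block (twelve terms
in all) — with correlated participant random intercepts and random slopes
on the pronunciation code. Coefficients are reported from a REML fit;
p-values use the Wald normal approximation on estimate/SE.

The null-evidence procedure fits, by maximum likelihood, a reduced
random-intercept model with and without the language × phonotactics
interaction, and converts the BIC difference into a Bayes factor in favour
of the null:  BF01 = exp((BIC_H1 − BIC_H0)/2),  P(H0 | data) =
BF01 / (1 + BF01) under equal prior odds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .contrasts import DEFAULT_CODEBOOK, Codebook, code
from .errors import AnalysisError

MIN_TRIALS_FOR_INCLUSION = 14  # one entire block: 2 warm-ups + 12 test trials

CONFIRMATORY_TERMS = (
    "(Intercept)",
    "Language",
    "Language[French]:Phonotactics",
    "Language[German]:Phonotactics",
    "Language[French]:Pronunciation",
    "Language[German]:Pronunciation",
    "Language[French]:Block",
    "Language[German]:Block",
    "Language[French]:Phonotactics:Pronunciation",
    "Language[German]:Phonotactics:Pronunciation",
    "Language[French]:Phonotactics:Block",
    "Language[German]:Phonotactics:Block",
)


@dataclass
class AnalysisTable:
    """Preprocessed test-trial rows with attached contrast codes."""

    data: pd.DataFrame  # participant, language, log_lt, lang/phon/pron/block codes
    codebook: dict
    n_excluded_participants: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_participants(self) -> int:
        return self.data["participant"].nunique()


@dataclass(frozen=True)
class Coefficient:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class FitResult:
    coefficients: dict[str, Coefficient]
    random: dict[str, float]
    loglik: float
    n_obs: int
    n_participants: int
    method: str  # "ML" | "REML"
    bic: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": name,
                    "estimate": c.estimate,
                    "se": c.se,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p": c.p,
                }
                for name, c in self.coefficients.items()
            ]
        )


@dataclass
class BayesComparison:
    bic_h0: float
    bic_h1: float

    @property
    def delta_bic(self) -> float:
        return self.bic_h1 - self.bic_h0

    @property
    def bf01(self) -> float:
        return math.exp(self.delta_bic / 2.0)

    @property
    def posterior_h0(self) -> float:
        return self.bf01 / (1.0 + self.bf01)


def posterior_from_bf(bf01: float) -> float:
    """Posterior probability of the null under equal prior odds."""
    if bf01 < 0:
        raise AnalysisError("a Bayes factor cannot be negative")
    return bf01 / (1.0 + bf01)


def preprocess(
    records: pd.DataFrame,
    codebook: Codebook = DEFAULT_CODEBOOK,
    min_trials: int = MIN_TRIALS_FOR_INCLUSION,
) -> AnalysisTable:
    """Trial-level records → analysis table.

    Participants are retained only if they completed at least ``min_trials``
    trials (one entire block, warm-ups included); partial second blocks are
    kept. Warm-up trials are dropped, looking times are natural-log
    transformed, and ±1 sum-contrast codes are attached per the codebook.
    """
    required = {"participant", "language", "block", "trial_type", "pronunciation", "phonotactics", "looking_time"}
    missing = required - set(records.columns)
    if missing:
        raise AnalysisError(f"records missing columns: {sorted(missing)}")
    counts = records.groupby("participant")["trial_index" if "trial_index" in records else "block"].count()
    keep = set(counts[counts >= min_trials].index)
    n_excluded = counts.size - len(keep)
    df = records[records["participant"].isin(keep)]
    df = df[df["trial_type"] == "test"].copy()
    if df.empty:
        raise AnalysisError("no participants retained after the inclusion rule")
    bad = df[~(df["looking_time"] > 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise AnalysisError(
            f"non-positive looking time for participant {row['participant']} "
            f"trial {row.get('trial_index', '?')}"
        )
    out = pd.DataFrame(
        {
            "participant": df["participant"].to_numpy(),
            "language": df["language"].to_numpy(),
            "block": df["block"].to_numpy(),
            "log_lt": np.log(df["looking_time"].to_numpy(dtype=float)),
            "lang_code": [code(codebook, "language", v) for v in df["language"]],
            "phon_code": [code(codebook, "phonotactics", v) for v in df["phonotactics"]],
            "pron_code": [code(codebook, "pronunciation", v) for v in df["pronunciation"]],
            "block_code": [code(codebook, "block", v) for v in df["block"]],
        }
    )
    return AnalysisTable(
        data=out,
        codebook={f: dict(m) for f, m in codebook.items()},
        n_excluded_participants=int(n_excluded),
    )


def _nested_design(df: pd.DataFrame, include_block: bool = True) -> pd.DataFrame:
    ind_fr = (df["language"] == "French").astype(float).to_numpy()
    ind_de = 1.0 - ind_fr
    phon = df["phon_code"].to_numpy()
    pron = df["pron_code"].to_numpy()
    cols = {
        "(Intercept)": np.ones(len(df)),
        "Language": df["lang_code"].to_numpy(),
        "Language[French]:Phonotactics": ind_fr * phon,
        "Language[German]:Phonotactics": ind_de * phon,
        "Language[French]:Pronunciation": ind_fr * pron,
        "Language[German]:Pronunciation": ind_de * pron,
    }
    if include_block:
        blk = df["block_code"].to_numpy()
        cols["Language[French]:Block"] = ind_fr * blk
        cols["Language[German]:Block"] = ind_de * blk
    cols["Language[French]:Phonotactics:Pronunciation"] = ind_fr * phon * pron
    cols["Language[German]:Phonotactics:Pronunciation"] = ind_de * phon * pron
    if include_block:
        blk = df["block_code"].to_numpy()
        cols["Language[French]:Phonotactics:Block"] = ind_fr * phon * blk
        cols["Language[German]:Phonotactics:Block"] = ind_de * phon * blk
    return pd.DataFrame(cols, index=df.index)


def _check_levels(df: pd.DataFrame) -> None:
    if df["language"].nunique() < 2:
        raise AnalysisError("both language groups must be present")
    for col in ("phon_code", "pron_code"):
        if df[col].nunique() < 2:
            raise AnalysisError(f"both levels of {col} must be present")


def _near_boundary(result, rtol: float = 1e-3) -> bool:
    """True when the RE covariance is (near-)singular relative to the scale."""
    cov = np.atleast_2d(np.asarray(result.cov_re))
    if not np.all(np.isfinite(cov)):
        return True
    eig = np.linalg.eigvalsh(cov)
    return bool(eig.min() < rtol * max(eig.max(), float(result.scale)))


# "MLE may be on the boundary" fires even on healthy interior fits, so only
# the stronger diagnostics count as evidence of a bad solution
_BOUNDARY_HINTS = ("positive definite", "singular")


def _fit_once(model, reml: bool, method: str, start_params=None):
    """One solver pass; returns (result|None, warning messages, suspicious)."""
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            result = model.fit(
                reml=reml, method=method, maxiter=5000, start_params=start_params
            )
        except (np.linalg.LinAlgError, ValueError):
            return None, [], True
    msgs = [
        str(w.message)
        for w in wlist
        if issubclass(w.category, (ConvergenceWarning, RuntimeWarning, UserWarning))
    ]
    if not (np.isfinite(result.llf) and np.all(np.isfinite(result.fe_params))):
        return None, msgs, True
    suspicious = _near_boundary(result) or any(
        hint in m.lower() for m in msgs for hint in _BOUNDARY_HINTS
    )
    return result, msgs, suspicious


def _fit_mixedlm(y, X, groups, exog_re, reml: bool):
    """Fit with a solver fallback chain; never raise on non-convergence.

    Quasi-Newton solvers routinely report convergence short of the optimum
    when the random-effects covariance is (near-)singular — common at
    infant-study sample sizes — so any suspicious solution triggers
    derivative-free fallbacks and a warm-started refinement, keeping the
    best log-likelihood found.
    """
    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    best = None
    best_msgs: list[str] = []
    any_suspicious = False
    for method in ("lbfgs", "powell", "nm"):
        candidate, msgs, suspicious = _fit_once(model, reml, method)
        if candidate is None:
            continue
        any_suspicious = any_suspicious or suspicious
        if best is None or candidate.llf > best.llf + 1e-8:
            best, best_msgs = candidate, msgs
        if candidate.converged and not suspicious:
            break
    if best is not None and (any_suspicious or _near_boundary(best, rtol=1e-2)):
        refined, msgs, _ = _fit_once(model, reml, "powell", start_params=best.params)
        if refined is not None and refined.llf > best.llf:
            best, best_msgs = refined, best_msgs + msgs
    if best is None:
        raise AnalysisError("mixed model could not be evaluated with any solver")
    return best, best_msgs


def _bic(loglik: float, k: int, n: int) -> float:
    return -2.0 * loglik + k * math.log(n)


def _fit_result(result, X: pd.DataFrame, n_participants: int, method: str, caught: list[str], random_names: dict[str, tuple[int, int]]) -> FitResult:
    z = stats.norm.ppf(0.975)
    coefficients: dict[str, Coefficient] = {}
    for i, name in enumerate(X.columns):
        est = float(result.fe_params.iloc[i])
        se = float(result.bse_fe.iloc[i])
        if se > 0 and np.isfinite(se):
            p = 2.0 * stats.norm.sf(abs(est / se))
        else:
            p = float("nan")
        coefficients[name] = Coefficient(est, se, est - z * se, est + z * se, p)
    random: dict[str, float] = {}
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    for rname, (i, j) in random_names.items():
        random[rname] = float(cov_re[i, j])
    random["residual_var"] = float(result.scale)
    k = X.shape[1] + len(random_names) + 1  # fixed + RE (co)variances + residual
    n = int(result.nobs)
    return FitResult(
        coefficients=coefficients,
        random=random,
        loglik=float(result.llf),
        n_obs=n,
        n_participants=n_participants,
        method=method,
        bic=_bic(float(result.llf), k, n),
        converged=bool(result.converged),
        warnings=caught,
    )


def fit_confirmatory(table: AnalysisTable, method: str = "REML") -> FitResult:
    """Nested sum-contrast mixed model with random intercept + pronunciation slope."""
    df = table.data
    _check_levels(df)
    X = _nested_design(df)
    Z = np.column_stack([np.ones(len(df)), df["pron_code"].to_numpy()])
    result, caught = _fit_mixedlm(
        df["log_lt"].to_numpy(), X, df["participant"].to_numpy(), Z, reml=(method == "REML")
    )
    return _fit_result(
        result,
        X,
        table.n_participants,
        method,
        caught,
        {
            "intercept_var": (0, 0),
            "intercept_slope_cov": (0, 1),
            "pronunciation_slope_var": (1, 1),
        },
    )


def fit_interaction_comparison(table: AnalysisTable) -> BayesComparison:
    """BIC evidence for/against the language × phonotactics interaction.

    Both models — log LT ~ language + phonotactics (+ interaction under H1)
    with a participant random intercept — are fit by maximum likelihood, as
    BICs of models differing in fixed effects are only comparable under ML.
    """
    df = table.data
    _check_levels(df)
    y = df["log_lt"].to_numpy()
    groups = df["participant"].to_numpy()
    Z = np.ones((len(df), 1))
    base = pd.DataFrame(
        {
            "(Intercept)": np.ones(len(df)),
            "Language": df["lang_code"].to_numpy(),
            "Phonotactics": df["phon_code"].to_numpy(),
        },
        index=df.index,
    )
    with_int = base.copy()
    with_int["Language:Phonotactics"] = base["Language"] * base["Phonotactics"]
    bics = {}
    for label, X in (("h0", base), ("h1", with_int)):
        result, _ = _fit_mixedlm(y, X, groups, Z, reml=False)
        k = X.shape[1] + 2  # fixed + intercept variance + residual variance
        bics[label] = _bic(float(result.llf), k, int(result.nobs))
    return BayesComparison(bic_h0=bics["h0"], bic_h1=bics["h1"])


def fit_per_block(table: AnalysisTable, method: str = "REML") -> dict[int, FitResult]:
    """Confirmatory structure minus the block terms, fit on each block separately.

    Within a single block each participant hears exactly one pronunciation,
    so the by-participant pronunciation slope is confounded with the random
    intercept; the per-block random structure is therefore intercept-only.
    """
    out: dict[int, FitResult] = {}
    for blk, df in table.data.groupby("block"):
        _check_levels(df)
        X = _nested_design(df, include_block=False)
        Z = np.ones((len(df), 1))
        result, caught = _fit_mixedlm(
            df["log_lt"].to_numpy(), X, df["participant"].to_numpy(), Z, reml=(method == "REML")
        )
        out[int(blk)] = _fit_result(
            result,
            X,
            df["participant"].nunique(),
            method,
            caught,
            {"intercept_var": (0, 0)},
        )
    return out


def descriptives(records: pd.DataFrame) -> pd.DataFrame:
    """Raw looking-time summaries per language × phonotactic condition.

    Means and SDs (seconds, untransformed) are computed over participant-level
    condition means. Preference counts tally participants whose mean looking
    time is longer for s-initial lists, longer for ʃ-initial lists, or tied.
    Output columns: language, condition, mean_s, sd_s, n_longer_s,
    n_longer_sh, n_tie.
    """
    if records.empty:
        raise AnalysisError("no records to summarise")
    df = records[records["trial_type"] == "test"] if "trial_type" in records else records
    part = (
        df.groupby(["language", "participant", "phonotactics"], sort=True)["looking_time"]
        .mean()
        .reset_index()
    )
    rows = []
    for language, ldf in part.groupby("language", sort=True):
        wide = ldf.pivot(index="participant", columns="phonotactics", values="looking_time")
        s = wide.get("s-initial")
        sh = wide.get("ʃ-initial")
        if s is not None and sh is not None:
            both = wide.dropna(subset=["s-initial", "ʃ-initial"])
            n_longer_s = int((both["s-initial"] > both["ʃ-initial"]).sum())
            n_longer_sh = int((both["ʃ-initial"] > both["s-initial"]).sum())
            n_tie = int((both["s-initial"] == both["ʃ-initial"]).sum())
        else:
            n_longer_s = n_longer_sh = n_tie = 0
        for condition, cdf in ldf.groupby("phonotactics", sort=True):
            vals = cdf["looking_time"].to_numpy()
            rows.append(
                {
                    "language": language,
                    "condition": condition,
                    "mean_s": float(np.mean(vals)),
                    "sd_s": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                    "n_longer_s": n_longer_s,
                    "n_longer_sh": n_longer_sh,
                    "n_tie": n_tie,
                }
            )
    return pd.DataFrame(rows)
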
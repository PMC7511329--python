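"""Lesion outcomes and the staged model pipeline linking play-fighting
network traits to skin lesions from later aggression.

Three Gaussian responses are modelled: the lesion count gained in the
dyadic contest (post - pre), the count gained in the 24 h after group
mixing (24 h - pre-mix) and the log-transformed fresh-lesion count 3 weeks
after mixing.  Each is fitted with a linear mixed model carrying the
study's systematic fixed effects (sex, socialisation treatment, attack
latency, plus context-specific covariates) and random intercepts for pen
nested in farrowing batch (plus contest dyad or mixing pen).  The staged
pipeline is: backward-eliminate systematic effects at p >= 0.1, prune
network traits correlated above |r| = 0.8, stepwise-select traits by AIC
on the fixed-effects model with VIF collinearity checks, then refit the
full mixed model and compare against the trait-free model with a
log-likelihood ratio test.

Mixed models are fitted with statsmodels MixedLM (all random intercepts
expressed as variance components over a single grouping, so nested and
crossed structures are handled uniformly).  Degrees of freedom for the
coefficient t-tests use a Satterthwaite approximation computed from the
REML profile (statsmodels does not provide one): for contrast c,
df = 2 (c' C(th) c)^2 / (g' A g) with C(th) the fixed-effect covariance at
the variance estimates th, g its finite-difference gradient in th and A
the inverse observed information of the restricted likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "LesionOutcome",
    "ModelSpec",
    "ModelResult",
    "compute_outcomes",
    "analysis_frame",
    "play_lesion_correlation",
    "prune_correlated",
    "fit_lmm",
    "stepwise_systematic",
    "stepwise_network_traits",
    "lrt",
]


@dataclass
class LesionOutcome:
    animal_id: str
    contest_delta: float
    mix24_delta: float
    mix3wk_log: float


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of one outcome model."""

    response: str
    fixed: tuple = ()
    random: tuple = ()
    estimation: str = "REML"  # REML | ML

    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"

    def with_fixed(self, fixed) -> "ModelSpec":
        return replace(self, fixed=tuple(fixed))


@dataclass
class Coefficient:
    estimate: float
    se: float
    t: float
    df: float
    p: float


@dataclass
class ModelResult:
    spec: ModelSpec
    coefficients: dict  # term -> Coefficient
    aic: float
    loglik: float
    n: int
    converged: bool = True
    singular: bool = False
    vcomp: dict = field(default_factory=dict)
    scale: float = float("nan")

    def coef_table(self) -> pd.DataFrame:
        rows = [
            {"term": t, "estimate": c.estimate, "se": c.se, "t": c.t, "df": c.df, "p": c.p}
            for t, c in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outcome preprocessing


def compute_outcomes(animals, transform: str = "log1p") -> list[LesionOutcome]:
    """Differenced and transformed lesion outcomes per animal.

    Contest and 24 h mixing responses are post - pre differences; the
    3-week fresh count is log-transformed (``log1p`` by default, since
    zero fresh-lesion counts occur; ``log`` requires positive counts).
    Animals missing a required time point are excluded with a warning.
    """
    if transform not in ("log", "log1p"):
        raise ValueError(f"transform must be log or log1p, got {transform!r}")
    out = []
    skipped = []
    for a in animals:
        lc = a.lesion_counts
        needed = ("pre_contest", "post_contest", "pre_mix", "mix_24h", "mix_3wk")
        if any(k not in lc for k in needed):
            skipped.append(a.id)
            continue
        three = lc["mix_3wk"]
        if transform == "log":
            if three <= 0:
                skipped.append(a.id)
                continue
            three_t = float(np.log(three))
        else:
            three_t = float(np.log1p(three))
        out.append(
            LesionOutcome(
                animal_id=a.id,
                contest_delta=float(lc["post_contest"] - lc["pre_contest"]),
                mix24_delta=float(lc["mix_24h"] - lc["pre_mix"]),
                mix3wk_log=three_t,
            )
        )
    if skipped:
        warnings.warn(f"excluded {len(skipped)} animal(s) with missing lesion counts", stacklevel=2)
    return out


def analysis_frame(animals, transform: str = "log1p") -> pd.DataFrame:
    """Modelling table: one row per animal with outcomes and covariates.

    Columns: the three responses, sex, treatment, attack_latency_s,
    batch/pen/litter ids and, when present in the metadata, dyad id,
    contestant weight difference, body weight and mixing-pen id.
    Attack latency stays missing (NaN) for animals that never attacked;
    model fits are complete-case on the terms they use.
    """
    outcomes = {o.animal_id: o for o in compute_outcomes(animals, transform)}
    rows = []
    for a in animals:
        if a.id not in outcomes:
            continue
        o = outcomes[a.id]
        extra = getattr(a, "extra", {}) or {}
        rows.append(
            {
                "animal_id": a.id,
                "contest_delta": o.contest_delta,
                "mix24_delta": o.mix24_delta,
                "mix3wk_log": o.mix3wk_log,
                "sex": a.sex,
                "treatment": a.treatment,
                "attack_latency_s": np.nan if a.attack_latency_s is None else a.attack_latency_s,
                "batch": a.batch,
                "pen_id": a.pen_id,
                "litter_id": a.litter_id,
                "body_weight_kg": a.body_weight_kg.get("contest", np.nan),
                "dyad_id": extra.get("dyad_id"),
                "weight_diff_kg": extra.get("weight_diff_kg", np.nan),
                "mix_pen_id": extra.get("mix_pen_id"),
            }
        )
    return pd.DataFrame(rows)


def play_lesion_correlation(events, animals, lesion_key: str = "soc_24h"):
    """Pearson correlation, per treatment, between socialisation-day play
    involvement and log-transformed lesions 24 h after socialisation.

    A non-significant correlation supports the scoring of these
    interactions as play rather than true aggression.  Returns
    ``(r_soc, p_soc, r_con, p_con)``.
    """
    if not events:
        raise ValueError("no events")
    day0 = min(ev.day for ev in events)
    counts: dict[str, int] = {a.id: 0 for a in animals}
    for ev in events:
        if ev.day != day0:
            continue
        for aid in (ev.initiator_id, ev.recipient_id):
            if aid in counts:
                counts[aid] += 1
    out = []
    for treatment in ("socialised", "control"):
        xs, ys = [], []
        for a in animals:
            if a.treatment != treatment or lesion_key not in a.lesion_counts:
                continue
            xs.append(counts[a.id])
            ys.append(np.log1p(a.lesion_counts[lesion_key]))
        if len(xs) < 3:
            raise ValueError(f"treatment {treatment}: fewer than 3 animals with data")
        r, p = stats.pearsonr(xs, ys)
        out.extend([float(r), float(p)])
    return tuple(out)


def prune_correlated(traits: pd.DataFrame, threshold: float = 0.8, method: str = "pearson"):
    """Greedy removal of trait columns correlated above ``threshold``.

    Pairs are visited by descending |r| and the later-listed column of each
    offending pair is dropped; deterministic given column order.  Constant
    columns are dropped up front with a warning.  Returns
    ``(reduced table, dropped column list)``.
    """
    traits = traits.copy()
    dropped = []
    for col in list(traits.columns):
        if traits[col].nunique(dropna=True) <= 1:
            warnings.warn(f"dropping constant trait {col!r}", stacklevel=2)
            traits = traits.drop(columns=[col])
            dropped.append(col)
    if traits.shape[1] < 2:
        return traits, dropped
    order = {c: i for i, c in enumerate(traits.columns)}
    while traits.shape[1] >= 2:
        corr = traits.corr(method=method).abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        if corr.values[i, j] <= threshold:
            break
        a, b = corr.index[i], corr.columns[j]
        victim = a if order[a] > order[b] else b
        traits = traits.drop(columns=[victim])
        dropped.append(victim)
    return traits, dropped


# ---------------------------------------------------------------------------
# mixed models


def _design(spec: ModelSpec, data: pd.DataFrame):
    """Complete-case design matrices and grouping indicators for a spec."""
    sub = data.copy()
    y_df, x_df = patsy.dmatrices(spec.formula(), sub, return_type="dataframe", NA_action="drop")
    sub = sub.loc[x_df.index]
    keep = sub[list(spec.random)].notna().all(axis=1) if spec.random else pd.Series(True, index=sub.index)
    sub = sub.loc[keep]
    y = np.asarray(y_df.loc[sub.index]).ravel()
    x = np.asarray(x_df.loc[sub.index])
    names = list(x_df.columns)
    z_mats = []
    for f in spec.random:
        codes, _ = pd.factorize(sub[f])
        z = np.zeros((len(sub), codes.max() + 1))
        z[np.arange(len(sub)), codes] = 1.0
        z_mats.append(z)
    return sub, y, x, names, z_mats


def _build_v(theta: np.ndarray, n: int, z_mats) -> np.ndarray:
    v = theta[0] * np.eye(n)
    for tau, z in zip(theta[1:], z_mats):
        v += tau * (z @ z.T)
    return v


def _reml_loglik(theta, y, x, z_mats) -> float:
    n, p = x.shape
    v = _build_v(theta, n, z_mats)
    try:
        cv = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2 * np.log(np.diag(cv)).sum()
    vi_x = np.linalg.solve(v, x)
    xtvx = x.T @ vi_x
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, vi_x.T @ y)
    resid = y - x @ beta
    quad = resid @ np.linalg.solve(v, resid)
    ll = float(-0.5 * (logdet_v + logdet_x + quad + (n - p) * np.log(2 * np.pi)))
    return ll if np.isfinite(ll) else -np.inf


def _ml_loglik(theta, y, x, z_mats) -> float:
    n = x.shape[0]
    v = _build_v(theta, n, z_mats)
    try:
        cv = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2 * np.log(np.diag(cv)).sum()
    vi_x = np.linalg.solve(v, x)
    beta = np.linalg.solve(x.T @ vi_x, vi_x.T @ y)
    resid = y - x @ beta
    quad = resid @ np.linalg.solve(v, resid)
    ll = float(-0.5 * (logdet_v + quad + n * np.log(2 * np.pi)))
    return ll if np.isfinite(ll) else -np.inf


def _direct_fit(y, x, z_mats, reml: bool):
    """Profile-likelihood fit of the variance parameters by bounded
    quasi-Newton; used when the statsmodels fit fails at a boundary."""
    from scipy.optimize import minimize

    obj = _reml_loglik if reml else _ml_loglik
    var0 = float(np.var(y)) or 1.0
    t0 = np.full(1 + len(z_mats), var0 / (1 + len(z_mats)))
    res = minimize(
        lambda t: -obj(t, y, x, z_mats),
        t0,
        method="L-BFGS-B",
        bounds=[(1e-8 * var0, None)] + [(0.0, None)] * len(z_mats),
    )
    theta = np.asarray(res.x)
    v = _build_v(theta, x.shape[0], z_mats)
    vi_x = np.linalg.solve(v, x)
    beta = np.linalg.solve(x.T @ vi_x, vi_x.T @ y)
    return theta, beta, float(-res.fun), bool(res.success)


def _fe_cov(theta, x, z_mats) -> np.ndarray:
    v = _build_v(theta, x.shape[0], z_mats)
    return np.linalg.inv(x.T @ np.linalg.solve(v, x))


def _satterthwaite_df(theta, y, x, z_mats) -> np.ndarray:
    """Per-coefficient Satterthwaite df at the variance estimates theta.

    Active components only (variances pinned at ~0 are held fixed); falls
    back to the residual df when the information matrix is degenerate.
    """
    n, p = x.shape
    resid_df = max(n - p, 1)
    active = [i for i, t in enumerate(theta) if i == 0 or t > 1e-8 * max(theta[0], 1e-12)]
    th = np.asarray(theta, dtype=float)

    def cdiag(t_active):
        full = th.copy()
        full[active] = t_active
        return np.diag(_fe_cov(full, x, z_mats))

    def ll(t_active):
        full = th.copy()
        full[active] = t_active
        return _reml_loglik(full, y, x, z_mats)

    t0 = th[active]
    h = np.maximum(1e-7, 1e-4 * np.abs(t0))
    m = len(t0)
    grad = np.zeros((m, p))
    for i in range(m):
        tp, tm = t0.copy(), t0.copy()
        tp[i] += h[i]
        tm[i] = max(tm[i] - h[i], 1e-12)
        grad[i] = (cdiag(tp) - cdiag(tm)) / (tp[i] - tm[i])
    hess = np.zeros((m, m))
    f0 = ll(t0)
    for i in range(m):
        for j in range(i, m):
            if i == j:
                tp, tm = t0.copy(), t0.copy()
                tp[i] += h[i]
                tm[i] = max(tm[i] - h[i], 1e-12)
                hess[i, i] = (ll(tp) - 2 * f0 + ll(tm)) / ((0.5 * (tp[i] - tm[i])) ** 2)
            else:
                tpp, tpm, tmp, tmm = t0.copy(), t0.copy(), t0.copy(), t0.copy()
                tpp[[i, j]] += [h[i], h[j]]
                tpm[i] += h[i]
                tpm[j] = max(tpm[j] - h[j], 1e-12)
                tmp[j] += h[j]
                tmp[i] = max(tmp[i] - h[i], 1e-12)
                tmm[i] = max(tmm[i] - h[i], 1e-12)
                tmm[j] = max(tmm[j] - h[j], 1e-12)
                hess[i, j] = hess[j, i] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (
                    (tpp[i] - tmm[i]) * (tpp[j] - tmm[j])
                )
    try:
        acov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return np.full(p, float(resid_df))
    c0 = cdiag(t0)
    dfs = np.empty(p)
    for c in range(p):
        g = grad[:, c]
        denom = float(g @ acov @ g)
        if denom <= 0 or not np.isfinite(denom):
            dfs[c] = resid_df
        else:
            dfs[c] = min(max(2 * c0[c] ** 2 / denom, 1.0), resid_df)
    return dfs


def _statsmodels_fit(spec: ModelSpec, sub: pd.DataFrame, reml: bool):
    """MixedLM fit returning (theta, beta, loglik, converged).

    When one random factor contains all others nested inside it (the
    study's structure: pen, dyad and mixing pen all sit within farrowing
    batch) it becomes the MixedLM grouping with the rest as variance
    components; otherwise a single constant group carries every factor as
    a variance component (crossed designs).  Returns ``theta=None`` if
    the fit errors out.
    """
    rand = list(spec.random)

    def nested_in(a: str, b: str) -> bool:
        return int(sub.groupby(a, observed=True)[b].nunique().max()) == 1

    group_factor = next(
        (f for f in rand if all(nested_in(g, f) for g in rand if g != f)), None
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if group_factor is not None:
                others = [f for f in rand if f != group_factor]
                vc = {f: f"0 + C({f})" for f in others} or None
                model = smf.mixedlm(
                    spec.formula(), sub, groups=group_factor, re_formula="1", vc_formula=vc
                )
                res = model.fit(reml=reml, method=["lbfgs", "cg"])
                by_name = dict(zip(list(model.exog_vc.names), np.asarray(res.vcomp, float)))
                by_name[group_factor] = float(np.asarray(res.cov_re)[0, 0])
            else:
                sub = sub.assign(_ones=1)
                vc = {f: f"0 + C({f})" for f in rand}
                model = smf.mixedlm(
                    spec.formula(), sub, groups="_ones", vc_formula=vc, re_formula="0"
                )
                res = model.fit(reml=reml, method=["lbfgs", "cg"])
                by_name = dict(zip(list(model.exog_vc.names), np.asarray(res.vcomp, float)))
        theta = np.concatenate([[res.scale], [by_name[f] for f in rand]])
        return theta, np.asarray(res.fe_params), float(res.llf), bool(res.converged)
    except (np.linalg.LinAlgError, ValueError):
        return None, None, -np.inf, False


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> ModelResult:
    """Fit one Gaussian linear mixed model.

    Random intercepts for every factor in ``spec.random`` are expressed as
    variance components over a single constant grouping, which handles
    nested (pen within batch, with unique pen labels) and crossed (contest
    dyad) structures alike.  REML fits report Satterthwaite-df t-tests;
    ML fits (used for AIC and likelihood-ratio tests) report z-tests.
    With no random terms the model reduces to OLS.
    """
    reml = spec.estimation.upper() == "REML"
    sub, y, x, names, z_mats = _design(spec, data)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"{spec.response}: {n} complete cases for {p} fixed-effect columns")

    if not spec.random:
        ols = sm.OLS(y, x).fit()
        coefs = {
            nm: Coefficient(float(b), float(se), float(t), float(n - p), float(pv))
            for nm, b, se, t, pv in zip(names, ols.params, ols.bse, ols.tvalues, ols.pvalues)
        }
        ll = float(ols.llf)
        k = p + 1
        return ModelResult(spec, coefs, aic=2 * k - 2 * ll, loglik=ll, n=n, scale=float(ols.scale))

    sub = sub.copy()
    theta, beta, ll, converged = _statsmodels_fit(spec, sub, reml)
    obj = _reml_loglik if reml else _ml_loglik
    suspect = theta is None
    if not suspect:
        ll = obj(theta, y, x, z_mats)  # same convention for every fit path
        if not np.isfinite(ll) or not converged:
            suspect = True
        else:
            # cheap probe: a clearly better likelihood near the reported
            # optimum means the optimizer stalled
            for i in range(len(theta)):
                for fac in (0.7, 1.4):
                    t = theta.copy()
                    t[i] = theta[i] * fac + (1e-6 if i > 0 else 0.0)
                    if obj(t, y, x, z_mats) > ll + 0.01:
                        suspect = True
                        break
                if suspect:
                    break
    if suspect:
        # refit the same profile likelihood directly (bounded quasi-Newton)
        direct = _direct_fit(y, x, z_mats, reml)
        if theta is None or not np.isfinite(ll) or (direct[2] > ll and direct[3]):
            theta, beta, ll, converged = direct
    singular = bool(np.any(theta[1:] <= 1e-8 * max(theta[0], 1e-12)))

    cov = _fe_cov(theta, x, z_mats)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    if reml:
        dfs = _satterthwaite_df(theta, y, x, z_mats)
        pvals = 2 * stats.t.sf(np.abs(tvals), dfs)
    else:
        dfs = np.full(p, np.inf)
        pvals = 2 * stats.norm.sf(np.abs(tvals))
    coefs = {
        nm: Coefficient(float(b), float(s), float(t), float(d), float(pv))
        for nm, b, s, t, d, pv in zip(names, beta, se, tvals, dfs, pvals)
    }
    k = p + len(theta)
    vcomp = {f: float(t) for f, t in zip(spec.random, theta[1:])}
    if singular:
        warnings.warn(
            f"{spec.response}: singular random-effect fit (a variance component is ~0)",
            stacklevel=2,
        )
    return ModelResult(
        spec,
        coefs,
        aic=2 * k - 2 * ll,
        loglik=ll,
        n=n,
        converged=converged,
        singular=singular,
        vcomp=vcomp,
        scale=float(theta[0]),
    )


# ---------------------------------------------------------------------------
# model selection


def _terms_in_interactions(fixed) -> set:
    prot = set()
    for term in fixed:
        if ":" in term or "*" in term:
            prot.add(term)
            for part in term.replace("*", ":").split(":"):
                prot.add(part.strip())
    return prot


def stepwise_systematic(
    spec: ModelSpec, data: pd.DataFrame, alpha_keep: float = 0.1, protected=()
) -> ModelSpec:
    """Backward elimination of systematic fixed effects at p >= ``alpha_keep``.

    The least significant removable term is dropped and the model refitted
    until every remaining term has p < ``alpha_keep``.  Terms named in
    ``protected``, and any term participating in a retained interaction,
    are never removed.
    """
    fixed = list(spec.fixed)
    protected = set(protected)
    while fixed:
        result = fit_lmm(spec.with_fixed(fixed), data)
        term_p = _term_pvalues(result, fixed)
        prot = protected | _terms_in_interactions(fixed)
        removable = {t: p for t, p in term_p.items() if t not in prot}
        if not removable:
            break
        worst, worst_p = max(removable.items(), key=lambda kv: kv[1])
        if worst_p < alpha_keep:
            break
        fixed.remove(worst)
    return spec.with_fixed(fixed)


def _term_pvalues(result: ModelResult, fixed) -> dict:
    """Min coefficient p per model term (a multi-level factor is kept or
    dropped as a whole, judged by its strongest level)."""
    out = {}
    for term in fixed:
        ps = [
            c.p
            for name, c in result.coefficients.items()
            if name != "Intercept" and _coef_matches_term(name, term)
        ]
        out[term] = min(ps) if ps else 1.0
    return out


def _coef_matches_term(coef_name: str, term: str) -> bool:
    base = coef_name.split("[")[0]
    canon = lambda t: ":".join(sorted(p.strip() for p in t.replace("*", ":").split(":")))
    return canon(base) == canon(term) or canon(coef_name) == canon(term)


def variance_inflation(data: pd.DataFrame, terms) -> dict:
    """VIF of each term's column(s) on the combined fixed-effect design."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    rhs = " + ".join(terms)
    x = patsy.dmatrix(rhs, data, return_type="dataframe", NA_action="drop")
    out = {}
    cols = list(x.columns)
    for i, col in enumerate(cols):
        if col == "Intercept":
            continue
        out[col] = float(variance_inflation_factor(np.asarray(x), i))
    return out


def stepwise_network_traits(
    spec: ModelSpec,
    candidates,
    data: pd.DataFrame,
    vif_threshold: float = 10.0,
):
    """Bidirectional AIC stepwise search over network-trait fixed effects.

    Starting from the systematic fixed-effects model (OLS, the search
    model), repeatedly apply the single add-or-drop move over the
    candidate traits that lowers AIC most; stop when no move improves.
    Perfectly collinear candidates are excluded before the search.
    Returns ``(spec with selected traits appended, VIF map)``; traits
    with VIF above ``vif_threshold`` are flagged with a warning.
    """
    candidates = list(candidates)
    base = [t for t in spec.fixed]
    # AIC comparisons require a common row set across candidate models
    used_cols = {
        part
        for term in base + candidates
        for part in term.replace("*", ":").split(":")
        if part in data.columns
    }
    data = data.dropna(subset=sorted(used_cols))
    usable = []
    for tr in candidates:
        cols = base + usable + [tr]
        x = patsy.dmatrix(" + ".join(cols) if cols else "1", data, NA_action="drop")
        if np.linalg.matrix_rank(np.asarray(x)) == x.shape[1]:
            usable.append(tr)
        else:
            warnings.warn(f"trait {tr!r} is collinear with the design; excluded", stacklevel=2)

    def aic_of(traits):
        ms = ModelSpec(spec.response, tuple(base + traits), random=(), estimation="ML")
        return fit_lmm(ms, data).aic

    selected: list = []
    current_aic = aic_of(selected)
    while True:
        moves = []
        for tr in usable:
            trial = selected + [tr] if tr not in selected else [t for t in selected if t != tr]
            moves.append((aic_of(trial), trial))
        if not moves:
            break
        best_aic, best = min(moves, key=lambda m: m[0])
        if best_aic >= current_aic - 1e-9:
            break
        selected, current_aic = best, best_aic
    vif = variance_inflation(data, base + selected) if selected else {}
    for col, v in vif.items():
        if v > vif_threshold:
            warnings.warn(f"VIF {v:.1f} for {col!r} exceeds {vif_threshold}", stacklevel=2)
    return spec.with_fixed(tuple(base + selected)), vif


def lrt(full: ModelResult, reduced: ModelResult):
    """Log-likelihood ratio test between nested ML fits on identical rows."""
    if full.spec.estimation.upper() != "ML" or reduced.spec.estimation.upper() != "ML":
        raise ValueError("likelihood-ratio test requires ML fits")
    if full.n != reduced.n:
        raise ValueError("models were fitted on different rows")
    df = len(full.coefficients) - len(reduced.coefficients)
    if df < 0 or not set(reduced.spec.fixed) <= set(full.spec.fixed):
        raise ValueError("models are not nested (reduced must be a submodel of full)")
    chi2 = max(2 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p
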
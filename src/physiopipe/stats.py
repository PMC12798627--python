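"""Rank-based tests, FDR/Holm correction, and mixed repeated-measures ANOVA.

The layer mirrors a JASP-style analysis battery: Wilcoxon signed-rank
tests with matched rank-biserial correlation (RBC) for pre/post changes,
Mann-Whitney U with RBC for group differences, Benjamini-Hochberg FDR
across dependent-variable families, mixed rmANOVA (within factor Time,
between factors Tech and Stim) with Mauchly's sphericity test,
Greenhouse-Geisser correction and generalized eta-squared, and
Holm-corrected paired post-hoc t-tests with Cohen's d.

Small samples use exact null distributions: the signed-rank p enumerates
all sign assignments for n <= 12 non-zero differences, and the U test
enumerates all group labelings when n1*n2 <= 100; mid-ranks make both
tie-robust.  Larger samples use the normal approximation with tie
correction and continuity correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    """One test: statistic, p (raw and adjusted), effect size, sizes."""

    test: str
    statistic: float
    df: tuple[float, ...] = ()
    p_raw: float = np.nan
    p_adjusted: float = np.nan
    adjust_method: str = "none"
    effect_size: float = np.nan
    effect_kind: str = ""
    n: tuple[int, ...] = ()
    term: str = ""
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "test": self.test,
            "term": self.term,
            "statistic": self.statistic,
            "df": "/".join(f"{v:g}" for v in self.df),
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "adjust_method": self.adjust_method,
            "effect_size": self.effect_size,
            "effect_kind": self.effect_kind,
            "n": "/".join(str(v) for v in self.n),
        }
        d.update(self.extras)
        return d


def _midranks(x: np.ndarray) -> np.ndarray:
    return sstats.rankdata(x, method="average")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with matched RBC


def wilcoxon_rbc(pre: np.ndarray, post: np.ndarray) -> StatResult:
    """Wilcoxon signed-rank test of post-pre with matched rank-biserial.

    Zero differences are dropped (Wilcoxon's method); |d| gets mid-ranks.
    RBC = (sum of positive ranks - sum of negative ranks) / (sum of all
    ranks): +1 when every participant increases, 0 under symmetry.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatResult("wilcoxon", np.nan, n=(0,),
                          extras={"note": "all differences zero; test undefined"})
    r = _midranks(np.abs(d))
    w_plus = float(r[d > 0].sum())
    w_minus = float(r[d < 0].sum())
    s = w_plus + w_minus
    rbc = (w_plus - w_minus) / s

    if n <= 12:
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        dist = masks @ r
        p = min(1.0, 2.0 * min((dist <= w_plus).mean(), (dist >= w_plus).mean()))
        z = np.nan
    else:
        mu = s / 2.0
        sigma = np.sqrt((r**2).sum()) / 2.0
        cc = 0.5 * np.sign(w_plus - mu)
        z = (w_plus - mu - cc) / sigma if sigma > 0 else np.nan
        p = 2.0 * sstats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return StatResult(
        "wilcoxon", w_plus, p_raw=float(p), effect_size=float(rbc),
        effect_kind="rbc_matched", n=(n,),
        extras={"z": float(z) if np.isfinite(z) else None, "exact": n <= 12},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U with RBC


def mann_whitney_rbc(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Mann-Whitney U test with rank-biserial effect size 2U/(n1 n2) - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    r = _midranks(pooled)
    r1 = float(r[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    rbc = 2.0 * u / (n1 * n2) - 1.0

    if n1 * n2 <= 100:
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(r, n1)), dtype=float
        )
        dist = sums - n1 * (n1 + 1) / 2.0
        p = min(1.0, 2.0 * min((dist <= u).mean(), (dist >= u).mean()))
        z = np.nan
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie)
        sigma = np.sqrt(sigma2)
        cc = 0.5 * np.sign(u - mu)
        z = (u - mu - cc) / sigma if sigma > 0 else np.nan
        p = 2.0 * sstats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return StatResult(
        "mann_whitney", u, p_raw=float(p), effect_size=float(rbc),
        effect_kind="rbc", n=(n1, n2),
        extras={"z": float(z) if np.isfinite(z) else None, "exact": n1 * n2 <= 100},
    )


# ---------------------------------------------------------------------------
# multiplicity corrections


def fdr_bh(
    p_values: np.ndarray, families: np.ndarray | None = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up, applied within each family label."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    fam = np.zeros(p.size) if families is None else np.asarray(families)
    out = np.empty_like(p)
    for f in pd.unique(fam):
        sel = fam == f
        finite = sel & np.isfinite(p)
        out[sel & ~np.isfinite(p)] = np.nan
        if finite.any():
            out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def holm(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        out[finite] = multipletests(p[finite], method="holm")[1]
    return out


def apply_fdr(results: list[StatResult], families: list | None = None) -> list[StatResult]:
    """Attach BH-adjusted p values to a family of results in place."""
    p = np.array([r.p_raw for r in results], dtype=float)
    adj = fdr_bh(p, None if families is None else np.asarray(families))
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
        r.adjust_method = "fdr_bh"
    return results


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA


_MODELS = {
    "time_only": (),
    "time_by_tech": ("tech",),
    "time_by_stim": ("stim",),
    "time_by_tech_by_stim": ("tech", "stim"),
}


def _effect_columns(labels: pd.Series) -> np.ndarray:
    """Sum-to-zero (effect) coding: levels-1 columns."""
    levels = sorted(pd.unique(labels))
    ncol = len(levels) - 1
    out = np.zeros((labels.size, ncol))
    for j, lev in enumerate(levels[:-1]):
        out[:, j] = np.where(labels == lev, 1.0, 0.0)
        out[labels == levels[-1], j] = -1.0
    return out


def _interactions(blocks: list[np.ndarray]) -> np.ndarray:
    """All pairwise column products between consecutive blocks (tensor)."""
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(out.shape[0], -1)
    return out


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float((y**2).sum())
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(((y - X @ beta) ** 2).sum())


def _type3_ss(y: np.ndarray, terms: dict[str, np.ndarray], base: np.ndarray) -> dict[str, float]:
    """Type-III sums of squares: RSS(model without term) - RSS(full)."""
    full = np.column_stack([base] + list(terms.values())) if terms else base
    rss_full = _rss(y, full)
    out = {}
    for name in terms:
        cols = [base] + [v for t, v in terms.items() if t != name]
        # clamp tiny negative differences from floating-point cancellation
        out[name] = max(_rss(y, np.column_stack(cols)) - rss_full, 0.0)
    return out, rss_full


def rm_anova_gg(data: pd.DataFrame, model: str = "time_only") -> list[StatResult]:
    """Mixed rmANOVA with sphericity handling and generalized eta-squared.

    ``data`` is long format with columns participant, timepoint, value and
    (as needed) tech / stim; one value per participant x timepoint after
    listwise deletion.  Between-subject effects are tested against the
    subject error, within effects (Time and its interactions) against the
    within error.  Mauchly's test is run on the pooled within-cell
    covariance; when it rejects (p < .05) and there are more than two
    timepoints, the Greenhouse-Geisser epsilon rescales the within dfs and
    the corrected p is used (both ps are recorded).  Effect sizes are
    generalized eta-squared: SS_effect / (SS_effect + SS_subject_error +
    SS_within_error).
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; one of {sorted(_MODELS)}")
    between = _MODELS[model]
    need = {"participant", "timepoint", "value", *between}
    missing = need - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    wide = data.pivot_table(
        index="participant", columns="timepoint", values="value", aggfunc="mean"
    ).sort_index(axis=1)
    n_before = wide.shape[0]
    wide = wide.dropna(axis=0)
    notes: list[str] = []
    if wide.shape[0] < n_before:
        notes.append(f"listwise deletion removed {n_before - wide.shape[0]} subjects")
    k = wide.shape[1]
    N = wide.shape[0]
    if k < 2:
        raise ValueError("need at least 2 timepoints")
    if N < 2:
        raise ValueError("need at least 2 complete subjects")

    subj_labels = data.drop_duplicates("participant").set_index("participant")
    labels = subj_labels.loc[wide.index]
    Y = wide.to_numpy(dtype=float)
    m = Y.mean(axis=1)

    # ---- between-subject stratum (on subject means, scaled by k)
    base = np.ones((N, 1))
    bet_blocks = {f: _effect_columns(labels[f]) for f in between}
    terms_b: dict[str, np.ndarray] = {}
    for r in range(1, len(between) + 1):
        for combo in itertools.combinations(between, r):
            terms_b[":".join(combo)] = _interactions([bet_blocks[f] for f in combo])
    ss_b, rss_b = _type3_ss(m, terms_b, base) if terms_b else ({}, _rss(m, base))
    ss_b = {t: v * k for t, v in ss_b.items()}
    p_bet = 1 + sum(v.shape[1] for v in terms_b.values())
    df_subj_err = N - p_bet
    if df_subj_err <= 0:
        raise ValueError("no residual degrees of freedom in the between stratum")
    ss_subj_err = rss_b * k

    # ---- within-subject stratum (deviations from subject means)
    dev = (Y - m[:, None]).ravel()  # subject-major
    tp = np.tile(np.arange(k), N)
    T = _effect_columns(pd.Series(tp))
    terms_w: dict[str, np.ndarray] = {"time": T}
    for name, cols in terms_b.items():
        rep = np.repeat(cols, k, axis=0)
        terms_w[f"time:{name}"] = _interactions([T, rep])
    ss_w, rss_w = _type3_ss(dev, terms_w, np.zeros((N * k, 0)))
    cells = int(np.prod([len(pd.unique(labels[f])) for f in between])) if between else 1
    df_w_err = (N - cells) * (k - 1)
    if df_w_err <= 0:
        raise ValueError("no residual degrees of freedom in the within stratum")
    ss_w_err = rss_w

    # ---- sphericity on the pooled within-cell covariance
    if between:
        cell = labels[list(between)].astype(str).agg("|".join, axis=1).to_numpy()
    else:
        cell = np.zeros(N)
    R = Y.copy()
    for c in pd.unique(cell):
        sel = cell == c
        R[sel] -= Y[sel].mean(axis=0)
    Sigma = R.T @ R / max(N - cells, 1)
    C = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    S = C.T @ Sigma @ C
    tr = np.trace(S)
    eps = 1.0 if k == 2 else float(tr**2 / ((k - 1) * (S * S).sum())) if tr > 0 else 1.0
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    if k == 2 or tr <= 0:
        mauchly_w, mauchly_p = 1.0, 1.0
    else:
        det = np.linalg.det(S)
        mauchly_w = float(det / (tr / (k - 1)) ** (k - 1)) if det > 0 else 0.0
        df_m = k * (k - 1) // 2 - 1
        nc = N - cells
        dd = 1 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6 * (k - 1) * nc)
        chi2 = -nc * dd * np.log(mauchly_w) if mauchly_w > 0 else np.inf
        mauchly_p = float(sstats.chi2.sf(chi2, df_m)) if df_m > 0 else 1.0
    use_gg = (mauchly_p < 0.05) and (k > 2)

    denom_g = ss_subj_err + ss_w_err
    results: list[StatResult] = []

    def _fstat(ss: float, df_e: float, ms_err: float) -> float:
        if ms_err <= 0:
            return np.inf if ss > 0 else np.nan
        return (ss / df_e) / ms_err

    ms_subj = ss_subj_err / df_subj_err
    for name, cols in terms_b.items():
        df_e = terms_b[name].shape[1]
        F = _fstat(ss_b[name], df_e, ms_subj)
        p = float(sstats.f.sf(F, df_e, df_subj_err))
        results.append(
            StatResult(
                "rm_anova", float(F), df=(float(df_e), float(df_subj_err)),
                p_raw=p, effect_size=float(ss_b[name] / (ss_b[name] + denom_g)),
                effect_kind="eta2_generalized", n=(N,), term=name,
                extras={"stratum": "between", "ss": ss_b[name],
                        "notes": "; ".join(notes)},
            )
        )

    ms_err = ss_w_err / df_w_err
    for name, cols in terms_w.items():
        df_e = cols.shape[1]
        F = _fstat(ss_w[name], df_e, ms_err)
        p_unc = float(sstats.f.sf(F, df_e, df_w_err))
        p_gg = float(sstats.f.sf(F, df_e * eps, df_w_err * eps))
        p = p_gg if use_gg else p_unc
        df_pair = (
            (float(df_e * eps), float(df_w_err * eps))
            if use_gg
            else (float(df_e), float(df_w_err))
        )
        results.append(
            StatResult(
                "rm_anova", float(F), df=df_pair, p_raw=p,
                effect_size=float(ss_w[name] / (ss_w[name] + denom_g)),
                effect_kind="eta2_generalized", n=(N,), term=name,
                extras={
                    "stratum": "within", "ss": ss_w[name],
                    "epsilon_gg": eps, "mauchly_w": mauchly_w,
                    "mauchly_p": mauchly_p, "p_uncorrected": p_unc,
                    "p_gg": p_gg, "gg_applied": use_gg,
                    "notes": "; ".join(notes),
                },
            )
        )
    return results


# ---------------------------------------------------------------------------
# Holm-corrected paired post-hocs


def holm_posthoc_paired(
    data: pd.DataFrame,
    pairs: list[tuple[int, int]],
    by: str | None = None,
) -> list[StatResult]:
    """Paired t-tests between timepoints, Holm-corrected across the family.

    ``data`` is the same long format as :func:`rm_anova_gg`.  With ``by``
    set (e.g. "stim"), contrasts are run within each group level.  Cohen's
    d for the paired design is mean(diff) / sd(diff).
    """
    wide = data.pivot_table(
        index=["participant"] + ([by] if by else []),
        columns="timepoint",
        values="value",
        aggfunc="mean",
    )
    groups = (
        [(lev, wide.xs(lev, level=by)) for lev in sorted(data[by].dropna().unique())]
        if by
        else [("", wide)]
    )
    results: list[StatResult] = []
    for lev, tab in groups:
        for t1, t2 in pairs:
            sub = tab[[t1, t2]].dropna()
            diff = (sub[t2] - sub[t1]).to_numpy(dtype=float)
            label = f"{lev + ': ' if lev else ''}t{t2} - t{t1}"
            if diff.size < 2 or diff.std(ddof=1) == 0:
                results.append(
                    StatResult("paired_t", np.nan, n=(diff.size,), term=label,
                               extras={"note": "zero-variance or too-few differences"}))
                continue
            tstat, p = sstats.ttest_rel(sub[t2], sub[t1])
            d = diff.mean() / diff.std(ddof=1)
            results.append(
                StatResult(
                    "paired_t", float(tstat), df=(float(diff.size - 1),),
                    p_raw=float(p), effect_size=float(d), effect_kind="cohens_d",
                    n=(diff.size,), term=label,
                )
            )
    adj = holm(np.array([r.p_raw for r in results], dtype=float))
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
        r.adjust_method = "holm"
    return results


def results_table(results: list[StatResult]) -> pd.DataFrame:
    """Flatten a list of results into a DataFrame (one test per row)."""
    return pd.DataFrame([r.as_dict() for r in results])
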
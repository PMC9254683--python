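"""Permutation two-factor repeated-measures ANOVA and outlier sensitivity.

The design is fully crossed within subjects: factor A is the lag-optimization
scheme (2 levels), factor B the data segment (5 levels), the response one
Fisher-Z spatial correlation per subject x cell.  Classical within-subject F
statistics come from the standard sum-of-squares decomposition with separate
subject x factor error strata; their null distributions are built by
permuting factor levels within subjects, so no Gaussianity or sphericity
assumption enters:

* factor A: A-levels permuted independently within every subject x B stratum;
* factor B: B-levels permuted within every subject x A stratum;
* interaction: the full A x B cell vector permuted within each subject.

All schemes are exact under the corresponding exchangeability null, and the
first two remain valid in the presence of the other main effect.  p-values
use the add-one estimator ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from lagcvr.parcel_stats import fdr_adjust

logger = logging.getLogger("lagcvr")

__all__ = [
    "RmDesign",
    "PermAnovaResult",
    "rm_anova_f",
    "permute_rm_anova",
    "simple_main_effects",
    "extreme_outlier_screen",
]


@dataclass
class RmDesign:
    """Complete two-way within-subject layout, response shaped (S, A, B)."""

    response: np.ndarray
    factor_a_levels: tuple = ("No-Opt", "Lag-Opt")
    factor_b_levels: tuple = ("BH+REST", "CDB+REST", "REST", "REST_BH", "REST_CDB")

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=np.float64)
        if self.response.ndim != 3:
            raise ValueError("response must be (subjects, A levels, B levels)")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("design has missing cells (non-finite response)")

    @property
    def shape(self):
        return self.response.shape

    @classmethod
    def from_long(cls, df, subject="subject", a="scheme", b="segment", value="fisher_z"):
        """Pivot a long-format table into the (S, A, B) response array."""
        a_levels = tuple(sorted(df[a].unique()))
        b_levels = tuple(sorted(df[b].unique()))
        subjects = sorted(df[subject].unique())
        wide = df.pivot_table(index=subject, columns=[a, b], values=value)
        resp = np.full((len(subjects), len(a_levels), len(b_levels)), np.nan)
        for i, s in enumerate(subjects):
            for j, al in enumerate(a_levels):
                for k, bl in enumerate(b_levels):
                    resp[i, j, k] = wide.loc[s, (al, bl)]
        return cls(resp, factor_a_levels=a_levels, factor_b_levels=b_levels)


def _f_stats(y):
    """Within-subject F statistics for arrays shaped (..., S, A, B).

    Vectorized over any leading axes (used for permutation batches).
    Degenerate 0/0 ratios (constant response) are returned as F = 0.
    """
    S, A, B = y.shape[-3:]
    m = y.mean(axis=(-1, -2, -3), keepdims=True)
    ms = y.mean(axis=(-1, -2), keepdims=True)
    ma = y.mean(axis=(-1, -3), keepdims=True)
    mb = y.mean(axis=(-2, -3), keepdims=True)
    msa = y.mean(axis=-1, keepdims=True)
    msb = y.mean(axis=-2, keepdims=True)
    mab = y.mean(axis=-3, keepdims=True)

    ss_a = B * S * ((ma - m) ** 2).sum(axis=(-1, -2, -3))
    ss_b = A * S * ((mb - m) ** 2).sum(axis=(-1, -2, -3))
    ss_ab = S * ((mab - ma - mb + m) ** 2).sum(axis=(-1, -2, -3))
    ss_sa = B * ((msa - ms - ma + m) ** 2).sum(axis=(-1, -2, -3))
    ss_sb = A * ((msb - ms - mb + m) ** 2).sum(axis=(-1, -2, -3))
    resid = y - msa - msb - mab + ms + ma + mb - m
    ss_sab = (resid**2).sum(axis=(-1, -2, -3))

    df_a, df_b = A - 1, B - 1
    df_ab = df_a * df_b
    df_sa, df_sb, df_sab = df_a * (S - 1), df_b * (S - 1), df_ab * (S - 1)

    def ratio(ss_num, df_num, ss_den, df_den):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_num / df_num) / (ss_den / df_den)
        zero = (np.asarray(ss_den) <= 1e-300) & (np.asarray(ss_num) <= 1e-300)
        f = np.where(zero, 0.0, f)
        return f

    return {
        "f_a": ratio(ss_a, df_a, ss_sa, df_sa),
        "f_b": ratio(ss_b, df_b, ss_sb, df_sb),
        "f_ab": ratio(ss_ab, df_ab, ss_sab, df_sab),
        "df": {"a": (df_a, df_sa), "b": (df_b, df_sb), "ab": (df_ab, df_sab)},
    }


def rm_anova_f(design: RmDesign):
    """Classical two-way within-subject F statistics for one design."""
    y = design.response if isinstance(design, RmDesign) else np.asarray(design)
    out = _f_stats(y)
    if np.ptp(y) == 0:
        logger.warning("constant response: all F statistics set to 0")
    return out


@dataclass
class PermAnovaResult:
    f_a: float
    f_b: float
    f_ab: float
    df: dict
    p_a: float
    p_b: float
    p_ab: float
    n_perm: int
    seed: int
    exhaustive: dict = field(default_factory=dict)
    pairwise: object = None


def _perm_null(y, rng, n_perm, effect, chunk=20000):
    """Null F distribution for one effect via stratified permutation."""
    S, A, B = y.shape
    obs = _f_stats(y)[f"f_{effect}"]
    count = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        tiled = np.broadcast_to(y, (m, S, A, B)).copy()
        if effect == "a":
            tiled = rng.permuted(tiled, axis=2)
        elif effect == "b":
            tiled = rng.permuted(tiled, axis=3)
        else:  # interaction: permute the full cell vector within subject
            flat = tiled.reshape(m, S, A * B)
            flat = rng.permuted(flat, axis=2)
            tiled = flat.reshape(m, S, A, B)
        f_perm = _f_stats(tiled)[f"f_{effect}"]
        count += int((f_perm >= obs - 1e-12).sum())
        done += m
    return float(obs), (1 + count) / (1 + n_perm)


def _exhaustive_possible(S, A, B, effect, n_perm):
    if effect == "a":
        log_n = S * B * math.log(math.factorial(A))
    elif effect == "b":
        log_n = S * A * math.log(math.factorial(B))
    else:
        log_n = S * math.log(math.factorial(A * B))
    return log_n <= math.log(max(n_perm, 2))


def _perm_null_exhaustive(y, effect):
    """Enumerate every stratified permutation (tiny designs only)."""
    S, A, B = y.shape
    obs = _f_stats(y)[f"f_{effect}"]
    if effect == "a":
        strata = [(s, slice(None), b) for s in range(S) for b in range(B)]
        perms = list(itertools.permutations(range(A)))
        axis_len = A
    elif effect == "b":
        strata = [(s, a, slice(None)) for s in range(S) for a in range(A)]
        perms = list(itertools.permutations(range(B)))
        axis_len = B
    else:
        strata = [(s,) for s in range(S)]
        perms = list(itertools.permutations(range(A * B)))
        axis_len = A * B
    count = 0
    total = 0
    for combo in itertools.product(range(len(perms)), repeat=len(strata)):
        yp = y.copy()
        for stratum, pi in zip(strata, combo):
            perm = perms[pi]
            if effect == "ab":
                s = stratum[0]
                flat = yp[s].reshape(axis_len)[list(perm)]
                yp[s] = flat.reshape(A, B)
            else:
                yp[stratum] = yp[stratum][list(perm)]
        total += 1
        if _f_stats(yp)[f"f_{effect}"] >= obs - 1e-12:
            count += 1
    return float(obs), count / total


def permute_rm_anova(design: RmDesign, n_perm=100_000, seed=0):
    """Permutation p-values for both main effects and the interaction.

    Falls back to exhaustive enumeration (logged) when the stratified
    permutation group for an effect is smaller than ``n_perm``.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be at least 999")
    y = design.response
    S, A, B = y.shape
    rng = np.random.default_rng(seed)
    out = {}
    exhaustive = {}
    for effect in ("a", "b", "ab"):
        if _exhaustive_possible(S, A, B, effect, n_perm):
            logger.info("effect %s: exhaustive enumeration used", effect)
            f_obs, p = _perm_null_exhaustive(y, effect)
            exhaustive[effect] = True
        else:
            f_obs, p = _perm_null(y, rng, n_perm, effect)
            exhaustive[effect] = False
        out[effect] = (f_obs, p)
    df = _f_stats(y)["df"]
    return PermAnovaResult(
        f_a=out["a"][0],
        f_b=out["b"][0],
        f_ab=out["ab"][0],
        df=df,
        p_a=out["a"][1],
        p_b=out["b"][1],
        p_ab=out["ab"][1],
        n_perm=int(n_perm),
        seed=int(seed),
        exhaustive=exhaustive,
    )


def simple_main_effects(
    design: RmDesign, factor="b", n_perm=10_000, seed=0, method="permutation", alpha=0.05
):
    """All pairwise level contrasts for one factor, FDR corrected.

    Each contrast collapses the other factor by subject mean and tests the
    paired difference — by within-subject sign-flip permutation (exhaustive
    when ``2**S <= n_perm``, which it is for small cohorts) or by a paired
    t-test (``method='parametric'``).
    """
    import pandas as pd
    from scipy import stats as sps

    y = design.response
    if factor == "a":
        collapsed = y.mean(axis=2)
        levels = design.factor_a_levels
    elif factor == "b":
        collapsed = y.mean(axis=1)
        levels = design.factor_b_levels
    else:
        raise ValueError("factor must be 'a' or 'b'")
    L = collapsed.shape[1]
    if L < 2:
        raise ValueError("need at least 2 levels for contrasts")
    S = collapsed.shape[0]
    rng = np.random.default_rng(seed)

    rows = []
    for i, j in itertools.combinations(range(L), 2):
        d = collapsed[:, i] - collapsed[:, j]
        obs = abs(d.mean())
        if method == "parametric":
            stat, p = sps.ttest_rel(collapsed[:, i], collapsed[:, j])
            stat = float(stat)
        else:
            if 2**S <= n_perm:
                signs = np.array(list(itertools.product([-1.0, 1.0], repeat=S)))
                null = np.abs((signs * d).mean(axis=1))
                p = float((null >= obs - 1e-15).mean())
                logger.info("contrast %s-%s: exhaustive sign flips", i, j)
            else:
                signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
                null = np.abs((signs * d).mean(axis=1))
                p = (1 + int((null >= obs - 1e-15).sum())) / (1 + n_perm)
            stat = float(d.mean())
        rows.append({"contrast": f"{levels[i]} vs {levels[j]}", "stat": stat, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy(), alpha=alpha)
    table["significant"] = table["p_fdr"] < alpha
    return table


@dataclass
class OutlierScreenResult:
    flags: np.ndarray  # (S, A, B) boolean
    results: dict  # variant name -> PermAnovaResult


def extreme_outlier_screen(design: RmDesign, n_perm=2000, seed=0):
    """Tukey 3xIQR extreme-outlier flags per design cell, plus sensitivity
    reruns of the permutation ANOVA.

    A value is extreme when it lies more than 3 IQR below Q1 or above Q3 of
    its cell (quartiles by linear interpolation, numpy default).  Three
    variants are run: full data, flagged subjects removed entirely, and
    flagged values replaced by the mean of the remaining values in the cell.
    """
    y = design.response
    S = y.shape[0]
    if S < 4:
        raise ValueError("need at least 4 subjects per cell for screening")
    q1 = np.quantile(y, 0.25, axis=0)
    q3 = np.quantile(y, 0.75, axis=0)
    iqr = q3 - q1
    flags = (y < q1 - 3 * iqr) | (y > q3 + 3 * iqr)

    results = {"full": permute_rm_anova(design, n_perm=n_perm, seed=seed)}

    flagged_subjects = np.where(flags.any(axis=(1, 2)))[0]
    if len(flagged_subjects) and S - len(flagged_subjects) >= 2:
        keep = np.setdiff1d(np.arange(S), flagged_subjects)
        results["subjects_removed"] = permute_rm_anova(
            RmDesign(y[keep], design.factor_a_levels, design.factor_b_levels),
            n_perm=n_perm,
            seed=seed,
        )
    if flags.any():
        repl = y.copy()
        for a in range(y.shape[1]):
            for b in range(y.shape[2]):
                cell_flags = flags[:, a, b]
                if cell_flags.any():
                    repl[cell_flags, a, b] = y[~cell_flags, a, b].mean()
        results["cell_mean_replaced"] = permute_rm_anova(
            RmDesign(repl, design.factor_a_levels, design.factor_b_levels),
            n_perm=n_perm,
            seed=seed,
        )
    return OutlierScreenResult(flags=flags, results=results)
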
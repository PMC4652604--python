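"""Classical twin genetic-variance analysis (GVA) and bootstrap ICC.

The GVA separates trait variance into genetic and environmental components
by contrasting monozygotic (MZ) and dizygotic (DZ) twin pairs, following
Christian et al.  One-way ANOVA with pair as the factor yields, per
zygosity, the among-pair (MSA) and within-pair (MSW) mean squares.  Two
estimators of genetic variance exist:

* **GWT** (within-pair): ``MSW_DZ - MSW_MZ``, tested with
  ``F = MSW_DZ / MSW_MZ`` on (n_DZ, n_MZ) degrees of freedom;
* **GCT** (combined among + within):
  ``[(MSA_MZ + MSW_DZ) - (MSA_DZ + MSW_MZ)] / 2``, tested with
  ``F = (MSA_MZ + MSW_DZ) / (MSA_DZ + MSW_MZ)`` where each sum of
  independent mean squares gets Satterthwaite-approximated degrees of
  freedom.

The F' test of equal total variances, ``(MSA_DZ + MSW_DZ) /
(MSA_MZ + MSW_MZ)`` (two-sided, Satterthwaite df), selects the estimator:
GCT when the totals differ at alpha = 0.2, GWT otherwise.  Prerequisites:
per-zygosity normality (Kolmogorov-Smirnov/Lilliefors) and equal MZ/DZ
means (t-test); a significant mean difference at 5 % indicates the trait is
associated with zygosity itself and the genetic test is not performed.
Analyses run on per-subject means over the two recording nights.  No
multiple-testing correction is applied.

ICCs use the one-way random-effects form for groups of size two,
``(MSA - MSW) / (MSA + MSW)``, for both within-pair resemblance (pair =
group, night-averaged values) and night-to-night stability (subject =
group).  Significance comes from a bootstrap null that breaks the pair
structure: values are resampled with replacement into pseudo-pairs until
1000 positive ICCs accumulate; the top 1/100th percentile of those is the
P = 0.01 threshold and their median is the similarity expected by chance.
Smaller samples produce higher thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, IterationCapError, ValidationError


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("pair_id", "zygosity", "member", "night", "value")


def subject_means(data: pd.DataFrame) -> pd.DataFrame:
    """Per-subject means over nights: columns pair_id, zygosity, member, value."""
    missing = [c for c in REQUIRED_COLUMNS[:3] if c not in data.columns]
    if missing or "value" not in data.columns:
        raise ValidationError(f"twin dataset lacks columns: {missing or ['value']}")
    if not np.all(np.isfinite(data["value"])):
        raise ValidationError("twin dataset contains non-finite values")
    g = (data.groupby(["pair_id", "zygosity", "member"], as_index=False)["value"]
         .mean())
    return g


def pair_matrix(data: pd.DataFrame, zygosity: str | None = None) -> np.ndarray:
    """``(n_pairs, 2)`` matrix of member values (night-averaged)."""
    g = subject_means(data)
    if zygosity is not None:
        g = g[g["zygosity"] == zygosity]
    wide = g.pivot(index="pair_id", columns="member", values="value")
    if wide.shape[1] != 2 or wide.isna().any().any():
        raise ValidationError("each pair needs exactly two members")
    return wide.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# ANOVA / ICC
# ---------------------------------------------------------------------------

def anova_mean_squares(pairs: np.ndarray):
    """One-way ANOVA mean squares with pair as the factor (2 members/pair).

    Returns ``(ms_among, ms_within)`` with n-1 and n degrees of freedom.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 2:
        raise ValidationError("need an (n_pairs >= 2, 2) array")
    n = x.shape[0]
    pair_means = x.mean(axis=1)
    ms_among = 2.0 * np.sum((pair_means - x.mean()) ** 2) / (n - 1)
    ms_within = np.sum((x - pair_means[:, None]) ** 2) / n
    return float(ms_among), float(ms_within)


def icc(pairs: np.ndarray) -> float:
    """One-way random-effects ICC(1,1) for groups of size two."""
    msa, msw = anova_mean_squares(pairs)
    if msa + msw == 0:
        raise ValidationError("all values equal: ICC undefined")
    return (msa - msw) / (msa + msw)


# ---------------------------------------------------------------------------
# GVA
# ---------------------------------------------------------------------------

@dataclass
class GVAResult:
    estimator: str                  # "GWT" or "GCT"
    ms_within: dict                 # zygosity -> MSW
    ms_among: dict                  # zygosity -> MSA
    f_prime_p: float
    genetic_estimate: float | None
    genetic_p: float | None
    prerequisites: dict             # ks_p per zygosity, means_t_p, passed


def _satterthwaite(ms1, df1, ms2, df2) -> float:
    """Effective df of the sum of two independent mean squares."""
    return (ms1 + ms2) ** 2 / (ms1 ** 2 / df1 + ms2 ** 2 / df2)


def _ks_normal_p(values: np.ndarray, method: str = "lilliefors") -> float:
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        return float(lilliefors(values, dist="norm")[1])
    z = (values - values.mean()) / values.std(ddof=1)
    return float(stats.kstest(z, "norm").pvalue)


def gva(data: pd.DataFrame, *, alpha_fprime: float = 0.2,
        alpha_prereq: float = 0.05, ks_method: str = "lilliefors") -> GVAResult:
    """Full genetic-variance analysis of a twin dataset.

    ``data`` holds rows (pair_id, zygosity in {MZ, DZ}, member in {a, b},
    night, value); per-subject means over nights are analysed.
    """
    mz = pair_matrix(data, "MZ")
    dz = pair_matrix(data, "DZ")
    if mz.shape[0] < 3 or dz.shape[0] < 3:
        raise InsufficientDataError("need at least 3 pairs per zygosity group")

    n_mz, n_dz = mz.shape[0], dz.shape[0]
    msa_mz, msw_mz = anova_mean_squares(mz)
    msa_dz, msw_dz = anova_mean_squares(dz)

    ks_p = {"MZ": _ks_normal_p(mz.ravel(), ks_method),
            "DZ": _ks_normal_p(dz.ravel(), ks_method)}
    means_t_p = float(stats.ttest_ind(mz.ravel(), dz.ravel(), equal_var=False).pvalue)
    passed = means_t_p >= alpha_prereq and all(p >= alpha_prereq for p in ks_p.values())
    prereq = {"ks_p": ks_p, "means_t_p": means_t_p, "passed": passed}

    # F' test of equal total variances (MSA + MSW), two-sided
    f_prime = (msa_dz + msw_dz) / (msa_mz + msw_mz)
    df_dz = _satterthwaite(msa_dz, n_dz - 1, msw_dz, n_dz)
    df_mz = _satterthwaite(msa_mz, n_mz - 1, msw_mz, n_mz)
    p_hi = stats.f.sf(f_prime, df_dz, df_mz)
    f_prime_p = float(2.0 * min(p_hi, 1.0 - p_hi))

    use_gct = f_prime_p < alpha_fprime
    estimator = "GCT" if use_gct else "GWT"

    genetic_estimate = genetic_p = None
    if passed:
        if use_gct:
            genetic_estimate = 0.5 * ((msa_mz + msw_dz) - (msa_dz + msw_mz))
            f_stat = (msa_mz + msw_dz) / (msa_dz + msw_mz)
            df_num = _satterthwaite(msa_mz, n_mz - 1, msw_dz, n_dz)
            df_den = _satterthwaite(msa_dz, n_dz - 1, msw_mz, n_mz)
            genetic_p = float(stats.f.sf(f_stat, df_num, df_den))
        else:
            genetic_estimate = msw_dz - msw_mz
            genetic_p = float(stats.f.sf(msw_dz / msw_mz, n_dz, n_mz))

    return GVAResult(
        estimator=estimator,
        ms_within={"MZ": msw_mz, "DZ": msw_dz},
        ms_among={"MZ": msa_mz, "DZ": msa_dz},
        f_prime_p=f_prime_p,
        genetic_estimate=genetic_estimate,
        genetic_p=genetic_p,
        prerequisites=prereq,
    )


# ---------------------------------------------------------------------------
# bootstrap ICC null
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    boot_p01: float        # top 1/100th percentile of the positive-ICC null
    boot_median: float     # positive ICC expected by chance
    n_boot_positive: int = 1000
    label: str = field(default="")

    def __post_init__(self):
        from .agreement import landis_koch_label

        if not self.label:
            self.label = landis_koch_label(self.icc)


def bootstrap_icc_null(values: np.ndarray, *, n_positive: int = 1000,
                       seed=None, max_draws: int = 10 ** 6,
                       batch: int = 2000, return_null: bool = False):
    """Positive-ICC bootstrap null for a flattened sample.

    Values are resampled with replacement (breaking the pair structure) into
    pseudo-pairs; the ICC of each resample is kept iff positive, until
    ``n_positive`` values accumulate.  Returns ``(boot_p01, boot_median)``,
    or ``(boot_p01, boot_median, null_sample)`` when ``return_null``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4 or v.size % 2:
        raise ValidationError("need an even number (>= 4) of values")
    if np.ptp(v) == 0:
        raise ValidationError("constant sample: ICC undefined")
    rng = np.random.default_rng(seed)
    n_pairs = v.size // 2
    collected = np.empty(0)
    drawn = 0
    while collected.size < n_positive:
        if drawn >= max_draws:
            raise IterationCapError(
                f"{collected.size} positive ICCs after {drawn} draws")
        b = min(batch, max_draws - drawn)
        sample = rng.choice(v, size=(b, n_pairs, 2), replace=True)
        pm = sample.mean(axis=2)
        msa = 2.0 * ((pm - sample.mean(axis=(1, 2))[:, None]) ** 2).sum(axis=1) / (n_pairs - 1)
        msw = ((sample - pm[:, :, None]) ** 2).sum(axis=(1, 2)) / n_pairs
        tot = msa + msw
        ok = tot > 0
        iccs = (msa[ok] - msw[ok]) / tot[ok]
        collected = np.concatenate([collected, iccs[iccs > 0]])
        drawn += b
    collected = collected[:n_positive]
    p01, med = float(np.percentile(collected, 99)), float(np.median(collected))
    if return_null:
        return p01, med, collected
    return p01, med


def icc_with_bootstrap(pairs: np.ndarray, *, n_positive: int = 1000,
                       seed=None) -> ICCResult:
    """ICC of the original sample plus its bootstrap null thresholds."""
    value = icc(pairs)
    p01, med = bootstrap_icc_null(np.asarray(pairs).ravel(),
                                  n_positive=n_positive, seed=seed)
    return ICCResult(icc=value, boot_p01=p01, boot_median=med,
                     n_boot_positive=n_positive)


def night_stability_matrix(data: pd.DataFrame, zygosity: str) -> np.ndarray:
    """``(n_subjects, 2)`` night-1/night-2 values for stability ICCs."""
    d = data[data["zygosity"] == zygosity]
    wide = d.pivot_table(index=["pair_id", "member"], columns="night", values="value")
    if wide.shape[1] != 2 or wide.isna().any().any():
        raise ValidationError("each subject needs exactly two nights")
    return wide.to_numpy(dtype=float)
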
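"""Replicate-level inference and summary statistics for mutation spectra.

Covers the statistical layer of a mutational-profiling study:

* Ames-table arithmetic — n-fold increase of revertant counts over the
  concurrent solvent control and the coefficient of variation;
* Dunnett's many-to-one multiple comparison test (two-sided, pooled
  variance) on per-10^6-bp class frequencies, with the joint max-|t|
  probability evaluated by deterministic Gauss quadrature;
* Student's t-test (two-sided, equal variance by default);
* PCA of standardised 6-class spectra with a fixed sign convention;
* MTSF — the maximum over doses of the mean total BS frequency — and its
  correlation (Spearman, and Pearson on log10 scale) with TD50
  carcinogenic-potency values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

if TYPE_CHECKING:
    import pandas as pd

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from numpy.polynomial.legendre import leggauss
from scipy import optimize, stats as sps


# ---------------------------------------------------------------- Ames table


def fold_increase(treated_mean: float, control_mean: float) -> float:
    """Ratio of treated to control mean revertant counts."""
    if control_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    return treated_mean / control_mean


def coefficient_of_variation(sd: float, mean: float) -> float:
    """sd / mean."""
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    return sd / mean


def round_sig(x: float, digits: int = 3) -> float:
    """Round to significant figures (table formatting convention)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(slots=True)
class AmesCounts:
    """Revertants/plate summary for one chemical at one dose (n replicates)."""

    mutagen: str
    dose: float
    mean: float
    sd: float
    n: int = 3

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("CV and SD need n >= 2")

    @property
    def cv(self) -> float:
        return coefficient_of_variation(self.sd, self.mean)


# ------------------------------------------------------------------- Dunnett


def _dunnett_max_abs_cdf(
    c: float, lambdas: np.ndarray, df: int, n_z: int = 96, n_u: int = 160
) -> float:
    """P(max_i |T_i| <= c) for Dunnett many-to-one comparisons.

    T_i = (Z_i*sqrt(1-l_i^2) - l_i*Z0)/U with l_i = sqrt(n_i/(n_i+n0)) and
    U = s/sigma from the pooled chi(df); integrates out Z0 (Gauss-Hermite)
    and U (Gauss-Legendre on an inverse-chi quantile range).
    """
    if c <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    rad = np.sqrt(1.0 - lam**2)

    z_nodes, z_w = hermegauss(n_z)  # weight exp(-z^2/2), total sqrt(2*pi)
    z_w = z_w / math.sqrt(2.0 * math.pi)

    if np.isinf(df):
        u_nodes = np.array([1.0])
        u_w = np.array([1.0])
    else:
        chi = sps.chi(df, scale=1.0 / math.sqrt(df))
        lo, hi = chi.ppf(1e-13), chi.isf(1e-13)
        x, w = leggauss(n_u)
        u_nodes = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        u_w = 0.5 * (hi - lo) * w * chi.pdf(u_nodes)

    # inner product over comparisons, vectorised on (u, z)
    U = u_nodes[:, None]
    Z = z_nodes[None, :]
    prod = np.ones((u_nodes.size, z_nodes.size))
    for l_i, r_i in zip(lam, rad):
        upper = (c * U + l_i * Z) / r_i
        lower = (-c * U + l_i * Z) / r_i
        prod *= sps.norm.cdf(upper) - sps.norm.cdf(lower)
    inner = prod @ z_w
    return float(np.clip(inner @ u_w, 0.0, 1.0))


def dunnett_critical_value(
    n_treated: int, df: int, lambdas: Sequence[float] | None = None, alpha: float = 0.05
) -> float:
    """Two-sided critical value c with P(max|T| > c) = alpha under the null."""
    if lambdas is None:
        lambdas = [math.sqrt(0.5)] * n_treated  # equal group sizes
    f = lambda c: _dunnett_max_abs_cdf(c, np.asarray(lambdas), df) - (1.0 - alpha)
    return float(optimize.brentq(f, 1e-6, 50.0, xtol=1e-10))


@dataclass
class DunnettResult:
    """Adjusted two-sided p-values for each treated group vs the shared control."""

    statistics: np.ndarray
    pvalues: np.ndarray
    df: int
    lambdas: np.ndarray


def dunnett_test(
    control: Sequence[float], treated_groups: Sequence[Sequence[float]]
) -> DunnettResult:
    """Dunnett's test: each treated group against one control, pooled variance.

    Two-sided; the adjusted p-value of group i is
    P(max_j |T_j| >= |t_i|) under the joint null, which keeps the
    family-wise error at the nominal level. Degenerate data (zero pooled
    variance) gives p = 1 for equal means and p = 0 otherwise.
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treated_groups]
    if len(groups) == 0:
        raise ValueError("at least one treated group is required")
    if control.size < 2 or any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2 replicates")

    n0 = control.size
    ns = np.array([g.size for g in groups])
    df = int(n0 + ns.sum() - (len(groups) + 1))
    ss = ((control - control.mean()) ** 2).sum() + sum(
        ((g - g.mean()) ** 2).sum() for g in groups
    )
    s2 = ss / df
    lambdas = np.sqrt(ns / (ns + n0))

    diffs = np.array([g.mean() - control.mean() for g in groups])
    if s2 == 0:
        t = np.where(diffs == 0, 0.0, np.inf)
    else:
        t = diffs / np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    pvals = np.array(
        [
            0.0
            if np.isinf(abs(ti))
            else 1.0 - _dunnett_max_abs_cdf(abs(ti), lambdas, df)
            for ti in t
        ]
    )
    return DunnettResult(statistics=t, pvalues=pvals, df=df, lambdas=lambdas)


def students_t(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> float:
    """Two-sided Student's t-test p-value (equal variance by default).

    Degenerate input (both groups constant) gives p = 1 for equal means,
    p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)


def significance_mark(p: float) -> str:
    """Figure-style annotation tiers: * <0.05, dagger <0.01, double-dagger <0.001."""
    if p < 0.001:
        return "‡"
    if p < 0.01:
        return "†"
    if p < 0.05:
        return "*"
    return ""


# ----------------------------------------------------------------------- PCA


@dataclass
class PCAResult:
    """PCA of standardised spectra.

    ``scores @ loadings.T`` reproduces the standardised data matrix;
    loadings are orthonormal columns; ``variance_proportions`` sum to 1.
    The sign of each component is fixed so its largest-magnitude loading
    is positive.
    """

    scores: np.ndarray  # (n_samples, k)
    loadings: np.ndarray  # (n_features, k)
    variance_proportions: np.ndarray  # (k,)
    feature_names: list[str]
    sample_names: list[str]
    dropped_features: list[str] = field(default_factory=list)
    standardized: np.ndarray | None = None

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T


def pca_spectra(
    matrix: np.ndarray,
    feature_names: Sequence[str] | None = None,
    sample_names: Sequence[str] | None = None,
    ddof: int = 1,
) -> PCAResult:
    """PCA of a samples x features spectrum matrix after standardisation.

    Each feature is centred and scaled to unit variance, so the
    decomposition is of the correlation structure; zero-variance features
    are dropped with a warning. Requires at least 3 samples.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 samples (rows)")
    n, p = X.shape
    feature_names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(p)
    ]
    sample_names = list(sample_names) if sample_names is not None else [
        f"s{i}" for i in range(n)
    ]

    sd = X.std(axis=0, ddof=ddof)
    keep = sd > 0
    dropped = [feature_names[j] for j in range(p) if not keep[j]]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    Xk = X[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / sd[keep]

    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # (p_kept, k) orthonormal columns
    proportions = pca.explained_variance_ratio_

    # sign convention: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]

    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_proportions=proportions,
        feature_names=[f for f, k in zip(feature_names, keep) if k],
        sample_names=sample_names,
        dropped_features=dropped,
        standardized=Z,
    )


# ---------------------------------------------------------------- MTSF, TD50


@dataclass
class DoseResponseProfile:
    """Replicate total BS frequencies per dose for one mutagen."""

    mutagen: str
    doses: dict[str, list[float]] = field(default_factory=dict)

    def add(self, dose_label: str, total_bs_frequency: float) -> None:
        self.doses.setdefault(dose_label, []).append(total_bs_frequency)

    @property
    def dose_means(self) -> dict[str, float]:
        return {d: float(np.mean(v)) for d, v in self.doses.items() if v}


def compute_mtsf(profile: DoseResponseProfile) -> float:
    """Maximum over doses of the mean replicate total BS frequency."""
    means = profile.dose_means
    if not means:
        raise ValueError(f"profile {profile.mutagen!r} has no dose with replicates")
    return max(means.values())


@dataclass(slots=True)
class TD50Record:
    """Most sensitive (lowest) TD50 carcinogenic potency, mg/kg/day."""

    mutagen: str
    td50: float

    def __post_init__(self) -> None:
        if self.td50 <= 0:
            raise ValueError("td50 must be > 0")


def load_ames_table(path: str | Path | None = None) -> "pd.DataFrame":
    """Read a revertant-count table (mutagen, dose, mean, sd, n).

    With no path, the packaged plate-count dataset for the 11 reference
    mutagens is returned.
    """
    import pandas as pd

    if path is None:
        path = resources.files("duplexprof").joinpath("data/ames_table1.tsv")
        with resources.as_file(path) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def ames_summary(table: "pd.DataFrame") -> "pd.DataFrame":
    """Per-row n-fold increase over the chemical's zero-dose control, plus CV.

    Fold values are reported to 3 significant figures and CVs to 3 decimal
    places, the usual plate-count table convention; zero-dose control rows
    get no fold value.
    """
    import pandas as pd

    rows = []
    for chemical, grp in table.groupby("chemical", sort=False):
        controls = grp[grp["dose_ug_per_plate"] == 0]
        if controls.empty:
            raise ValueError(f"chemical {chemical!r} has no zero-dose control row")
        control_mean = float(controls["mean_revertants"].iloc[0])
        for r in grp.itertuples(index=False):
            dose = float(r.dose_ug_per_plate)
            fold = (
                None
                if dose == 0
                else round_sig(fold_increase(float(r.mean_revertants), control_mean), 3)
            )
            cv = round(
                coefficient_of_variation(float(r.sd_revertants), float(r.mean_revertants)),
                3,
            )
            rows.append(
                {
                    "group": getattr(r, "group", ""),
                    "chemical": chemical,
                    "dose_ug_per_plate": dose,
                    "mean_revertants": float(r.mean_revertants),
                    "sd_revertants": float(r.sd_revertants),
                    "n": int(r.n),
                    "n_fold_increase": fold,
                    "cv": cv,
                }
            )
    return pd.DataFrame(rows)


def td50_correlation(
    mtsf: Mapping[str, float], td50: Mapping[str, float] | Sequence[TD50Record]
) -> dict[str, float]:
    """Correlation of MTSF with TD50 over mutagens present in both tables.

    Reports Spearman's rho and Pearson's r on log10-transformed values
    (neither privileged; both are standard for potency data spanning
    decades). Negative values mean higher mutation burden goes with lower
    (more potent) TD50. A constant input leaves Pearson undefined (NaN).
    """
    if not isinstance(td50, Mapping):
        td50 = {r.mutagen: r.td50 for r in td50}
    common = sorted(set(mtsf) & set(td50))
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired mutagens, got {len(common)}")
    x = np.array([mtsf[m] for m in common], dtype=float)
    y = np.array([td50[m] for m in common], dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("MTSF and TD50 must be positive for log10 correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> NaN, reported as such
        rho, rho_p = sps.spearmanr(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r, r_p = float("nan"), float("nan")
    else:
        r, r_p = sps.pearsonr(np.log10(x), np.log10(y))
    return {
        "n": len(common),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "pearson_r_log10": float(r),
        "pearson_p_log10": float(r_p),
    }
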
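"""Covariate-adjusted linear association of phenotypes with region states.

For every detected region a multiple linear regression

    phenotype ~ intercept + state + covariates

is fitted by ordinary least squares under an additive genetic model: the
region state enters as one signed-dose column (−2…+2).  Coefficients and
standard errors come from the normal equations solved by Gaussian
elimination with partial pivoting; the state coefficient's two-sided
p-value from a Student t-test with ``df = n − k`` (k regression columns
including the intercept).  Genome-wide significance is Bonferroni:
``p < alpha / M`` with ``M`` the number of regions actually tested.

The model/results pair :class:`CnvrGwas` / :class:`CnvrGwasResults` is the
primary interface; :func:`run_gwas` is a functional wrapper over it.
Missing data are handled complete-case per region: a subject is used iff
the response, the state and every covariate are observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cnvr_detection import CnvrStateMatrix
from .errors import (
    CollinearityError,
    ConfigError,
    InsufficientDataError,
    MonomorphicRegionError,
    ValidationError,
)
from .io_formats import PhenotypeTable, GenotypeTable, SnpMarker, chromosome_sort_key

__all__ = [
    "SubjectFilter",
    "AssociationConfig",
    "AssociationResult",
    "CombinedAssociationResult",
    "OlsFit",
    "apply_filters",
    "build_design_matrix",
    "fit_ols",
    "t_test_pvalue",
    "bonferroni_threshold",
    "run_gwas",
    "run_combined_snp_cnvr",
    "CnvrGwas",
    "CnvrGwasResults",
]

_PIVOT_RTOL = 1e-10


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_FILTER_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
    "!=": lambda a, b: a != b,
}


@dataclass(frozen=True)
class SubjectFilter:
    """Restrict the analysis to subjects satisfying ``column op value``.

    Subjects missing the filtered column never satisfy a filter.
    """

    column: str
    op: str
    value: float

    def __post_init__(self):
        if self.op not in _FILTER_OPS:
            raise ConfigError(f"unknown filter operator {self.op!r}; use one of {sorted(_FILTER_OPS)}")

    @classmethod
    def parse(cls, expression: str) -> "SubjectFilter":
        """Parse e.g. ``"sex==1"`` or ``"age >= 40"``."""
        for op in ("<=", ">=", "==", "!=", "<", ">"):
            if op in expression:
                column, _, value = expression.partition(op)
                column = column.strip()
                if not column:
                    break
                try:
                    return cls(column, op, float(value))
                except ValueError:
                    raise ConfigError(f"non-numeric filter value in {expression!r}") from None
        raise ConfigError(f"cannot parse filter expression {expression!r}")

    def mask(self, phenos: PhenotypeTable) -> np.ndarray:
        values = phenos.column(self.column).to_numpy()
        with np.errstate(invalid="ignore"):
            out = _FILTER_OPS[self.op](values, self.value)
        return np.asarray(out, dtype=bool) & ~np.isnan(values)


@dataclass
class AssociationConfig:
    """What to regress: response, adjustment covariates, alpha, filters."""

    phenotype: str
    covariates: tuple = ()
    alpha: float = 0.05
    filters: tuple = ()
    include_snps: bool = False

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        self.filters = tuple(self.filters)
        if self.phenotype in self.covariates:
            raise ConfigError(f"phenotype {self.phenotype!r} cannot also be a covariate")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """Per-region regression result for the state term."""

    region_id: str
    chromosome: str
    start_pos: int
    end_pos: int
    frequency: float
    n: int
    beta: float
    se: float
    t_stat: float
    p_value: float
    df: int
    significant: bool = False
    catalog_hit: bool = False
    covariate_betas: dict = field(default_factory=dict)

    def conf_int(self, level: float = 0.95):
        """Equal-tailed confidence interval for the state coefficient."""
        if not 0.0 < level < 1.0:
            raise ConfigError(f"level must be in (0,1), got {level}")
        half = stats.t.ppf(0.5 + level / 2.0, self.df) * self.se
        return (self.beta - half, self.beta + half)


@dataclass
class CombinedAssociationResult:
    """Joint SNP + region-state model for one (region, SNP) pair."""

    region_id: str
    marker_id: str
    chromosome: str
    position: int
    n: int
    df: int
    snp_beta: float
    snp_se: float
    snp_p: float
    state_beta: Optional[float]
    state_se: Optional[float]
    state_p: Optional[float]
    f_stat: float
    f_df: int
    f_p: float
    significant: bool = False


@dataclass
class OlsFit:
    """Least-squares fit: coefficients, standard errors and bookkeeping."""

    params: np.ndarray
    bse: np.ndarray
    df_resid: int
    rss: float
    sigma2: float
    columns: tuple


# ---------------------------------------------------------------------------
# Core numerics
# ---------------------------------------------------------------------------


def _gauss_jordan_inverse(a: np.ndarray, columns) -> np.ndarray:
    """Invert a symmetric k×k matrix by Gauss-Jordan elimination with
    partial pivoting; raise :class:`CollinearityError` on a tiny pivot."""
    k = a.shape[0]
    aug = np.concatenate([a.astype(float).copy(), np.eye(k)], axis=1)
    tol = _PIVOT_RTOL * max(np.abs(a).max(), 1e-300)
    for j in range(k):
        pivot_row = j + int(np.argmax(np.abs(aug[j:, j])))
        if abs(aug[pivot_row, j]) < tol:
            name = columns[j] if columns and j < len(columns) else f"column {j}"
            raise CollinearityError(
                f"design matrix is singular or nearly so at {name!r} "
                f"(pivot {aug[pivot_row, j]:.3e})",
                columns=(name,),
            )
        if pivot_row != j:
            aug[[j, pivot_row]] = aug[[pivot_row, j]]
        aug[j] /= aug[j, j]
        for i in range(k):
            if i != j and aug[i, j] != 0.0:
                aug[i] -= aug[i, j] * aug[j]
    return aug[:, k:]


def fit_ols(X: np.ndarray, y: np.ndarray, columns: Sequence[str] = ()) -> OlsFit:
    """Ordinary least squares via the normal equations.

    Solves ``(XᵀX) β = Xᵀy`` by Gaussian elimination with partial pivoting
    and returns coefficients, standard errors
    ``sqrt(s² · diag((XᵀX)⁻¹))`` with ``s² = RSS/(n−k)``, and ``df = n−k``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-dimensional")
    n, k = X.shape
    if y.shape != (n,):
        raise ValidationError(f"y must have shape ({n},), got {y.shape}")
    if n <= k:
        raise InsufficientDataError(f"insufficient observations: n={n} <= k={k}")
    xtx = X.T @ X
    xty = X.T @ y
    inv = _gauss_jordan_inverse(xtx, tuple(columns))
    params = inv @ xty
    resid = y - X @ params
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    diag = np.clip(np.diag(inv), 0.0, None)
    bse = np.sqrt(sigma2 * diag)
    return OlsFit(params=params, bse=bse, df_resid=df, rss=rss, sigma2=sigma2,
                  columns=tuple(columns) or tuple(f"x{i}" for i in range(k)))


def t_test_pvalue(beta: float, se: float, df: int) -> float:
    """Two-sided Student-t p-value, ``p = 2·P(T_df ≥ |beta/se|)``.

    A perfect fit (``se = 0``) yields 0 for a nonzero coefficient and 1 for a
    zero one.
    """
    if df < 1:
        raise ConfigError(f"df must be >= 1, got {df}")
    if se < 0:
        raise ConfigError(f"se must be >= 0, got {se}")
    if se == 0.0:
        return 0.0 if beta != 0.0 else 1.0
    return float(2.0 * stats.t.sf(abs(beta / se), df))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance cut-off ``alpha / m`` for ``m`` tests."""
    if m < 1:
        raise ConfigError(f"number of tests must be >= 1, got {m}")
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must be in (0,1), got {alpha}")
    return alpha / m


# ---------------------------------------------------------------------------
# Subject selection and design
# ---------------------------------------------------------------------------


def apply_filters(phenos: PhenotypeTable, filters: Sequence[SubjectFilter]) -> list[str]:
    """Subjects satisfying *all* filters, in table order."""
    mask = np.ones(len(phenos), dtype=bool)
    for f in filters:
        mask &= f.mask(phenos)
    return [s for s, keep in zip(phenos.subject_ids, mask) if keep]


def build_design_matrix(
    state_row: pd.Series,
    phenos: PhenotypeTable,
    cfg: AssociationConfig,
    subjects: Sequence[str],
):
    """Assemble (X, y, column names, used subject ids) for one region.

    Columns are ``[intercept, state, *covariates]``; rows are the subjects
    with complete data for the response, the state and every covariate.
    """
    subjects = list(subjects)
    if not subjects:
        raise InsufficientDataError("no subjects to analyse")
    sub = phenos.frame.loc[subjects]
    y = sub[_require_column(phenos, cfg.phenotype)].to_numpy(dtype=float)
    cov = np.column_stack(
        [sub[_require_column(phenos, c)].to_numpy(dtype=float) for c in cfg.covariates]
    ) if cfg.covariates else np.empty((len(subjects), 0))
    state = state_row.reindex(subjects).to_numpy(dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(state)
    if cov.shape[1]:
        mask &= ~np.isnan(cov).any(axis=1)
    y, state, cov = y[mask], state[mask], cov[mask]
    used = [s for s, keep in zip(subjects, mask) if keep]
    if state.size and state.min() == state.max():
        raise MonomorphicRegionError(
            f"monomorphic: state constant ({state[0] if state.size else 'empty'}) "
            "in the analysed subjects"
        )
    names = ("intercept", "state", *cfg.covariates)
    X = np.column_stack([np.ones(len(y)), state, cov])
    if len(y) <= X.shape[1]:
        raise InsufficientDataError(
            f"insufficient observations: n={len(y)} <= k={X.shape[1]}"
        )
    return X, y, names, used


def _require_column(phenos: PhenotypeTable, name: str) -> str:
    if name not in phenos.frame.columns:
        raise ConfigError(
            f"unknown phenotype column {name!r}; available: {sorted(phenos.columns)}"
        )
    return name


# ---------------------------------------------------------------------------
# The model / results pair
# ---------------------------------------------------------------------------


class CnvrGwas:
    """Per-region association model over a state matrix and phenotype table.

    Parameters
    ----------
    states : CnvrStateMatrix
        Regions × subjects signed-dose states from the detection step.
    phenotypes : PhenotypeTable
        Response and covariate columns, indexed by subject.
    config : AssociationConfig
        Response name, covariates, alpha and subject filters.

    ``fit()`` runs one OLS per testable region and returns a
    :class:`CnvrGwasResults`.
    """

    def __init__(self, states: CnvrStateMatrix, phenotypes: PhenotypeTable,
                 config: AssociationConfig):
        self.states = states
        self.phenotypes = phenotypes
        self.config = config
        _require_column(phenotypes, config.phenotype)
        for c in config.covariates:
            _require_column(phenotypes, c)

    def fit(self) -> "CnvrGwasResults":
        cfg = self.config
        eligible = set(apply_filters(self.phenotypes, cfg.filters))
        subjects = [s for s in self.states.subject_ids if s in eligible]
        if not subjects:
            raise InsufficientDataError(
                "no subjects left after filtering / intersection with the state matrix"
            )
        sub = self.phenotypes.frame.loc[subjects]
        y_all = sub[cfg.phenotype].to_numpy(dtype=float)
        cov_all = (
            np.column_stack([sub[c].to_numpy(dtype=float) for c in cfg.covariates])
            if cfg.covariates
            else np.empty((len(subjects), 0))
        )
        base_mask = ~np.isnan(y_all)
        if cov_all.shape[1]:
            base_mask &= ~np.isnan(cov_all).any(axis=1)
        state_mat = self.states.frame[subjects].to_numpy(dtype=float)
        names = ("intercept", "state", *cfg.covariates)
        ones = np.ones(len(subjects))

        results: list[AssociationResult] = []
        skipped: list[tuple[str, str]] = []
        for region, srow in zip(self.states.regions, state_mat):
            mask = base_mask & ~np.isnan(srow)
            n = int(mask.sum())
            if n == 0:
                skipped.append((region.region_id, "no complete observations"))
                continue
            sv = srow[mask]
            if sv.min() == sv.max():
                skipped.append((region.region_id, "monomorphic"))
                continue
            X = np.column_stack([ones[mask], sv, cov_all[mask]])
            if n <= X.shape[1]:
                skipped.append((region.region_id, "insufficient observations"))
                continue
            try:
                fit = fit_ols(X, y_all[mask], columns=names)
            except CollinearityError as exc:
                skipped.append((region.region_id, f"collinear: {exc}"))
                continue
            beta, se = float(fit.params[1]), float(fit.bse[1])
            t_stat = beta / se if se > 0 else math.copysign(math.inf, beta) if beta else 0.0
            results.append(
                AssociationResult(
                    region_id=region.region_id,
                    chromosome=region.chromosome,
                    start_pos=region.start_pos,
                    end_pos=region.end_pos,
                    frequency=region.frequency,
                    n=n,
                    beta=beta,
                    se=se,
                    t_stat=t_stat,
                    p_value=t_test_pvalue(beta, se, fit.df_resid),
                    df=fit.df_resid,
                    covariate_betas={
                        name: float(b)
                        for name, b in zip(names, fit.params)
                        if name != "state"
                    },
                )
            )
        if not results:
            raise InsufficientDataError(
                "no testable regions: " + "; ".join(f"{r}: {why}" for r, why in skipped[:5])
            )
        res = CnvrGwasResults(results, skipped, alpha=cfg.alpha, n_subjects=len(subjects))
        return res


class CnvrGwasResults:
    """Fitted per-region associations with Bonferroni bookkeeping.

    Attributes
    ----------
    results : list of AssociationResult, sorted by genomic position
    skipped : list of (region_id, reason)
    m_tested : number of regions actually tested (the Bonferroni ``M``)
    bonferroni : the significance cut-off ``alpha / m_tested``
    """

    def __init__(self, results, skipped, alpha: float, n_subjects: int):
        self.results = sorted(
            results, key=lambda r: (chromosome_sort_key(r.chromosome), r.start_pos)
        )
        self.skipped = list(skipped)
        self.n_subjects = n_subjects
        self.m_tested = len(self.results)
        self._alpha = None
        self.set_alpha(alpha)

    @property
    def alpha(self) -> float:
        return self._alpha

    @property
    def bonferroni(self) -> float:
        return bonferroni_threshold(self._alpha, self.m_tested)

    def set_alpha(self, alpha: float) -> None:
        """Re-flag significance for a new alpha without refitting."""
        if not 0.0 < alpha < 1.0:
            raise ConfigError(f"alpha must be in (0,1), got {alpha}")
        self._alpha = alpha
        thr = self.bonferroni
        for r in self.results:
            r.significant = r.p_value < thr

    def significant_results(self) -> list[AssociationResult]:
        return [r for r in self.results if r.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.results],
                "chromosome": [r.chromosome for r in self.results],
                "start": [r.start_pos for r in self.results],
                "end": [r.end_pos for r in self.results],
                "frequency": [r.frequency for r in self.results],
                "n": [r.n for r in self.results],
                "beta": [r.beta for r in self.results],
                "se": [r.se for r in self.results],
                "t_stat": [r.t_stat for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "df": [r.df for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary with the strongest associations."""
        lines = [
            "CNV region association results",
            "==============================",
            f"regions tested     : {self.m_tested}",
            f"regions skipped    : {len(self.skipped)}",
            f"subjects (filtered): {self.n_subjects}",
            f"alpha              : {self._alpha:g}",
            f"Bonferroni cut-off : {self.bonferroni:.3e}",
            f"significant regions: {len(self.significant_results())}",
            "",
            f"{'region':<24} {'freq':>6} {'n':>5} {'beta':>9} {'se':>8} "
            f"{'t':>7} {'p':>10} sig",
        ]
        for r in sorted(self.results, key=lambda r: r.p_value)[:top]:
            lines.append(
                f"{r.region_id:<24} {r.frequency:>6.3f} {r.n:>5d} {r.beta:>9.4f} "
                f"{r.se:>8.4f} {r.t_stat:>7.2f} {r.p_value:>10.3e} "
                f"{'*' if r.significant else ''}"
            )
        return "\n".join(lines)

    def manhattan(self, spec, **kwargs):
        """Render a Manhattan plot of these results (see ``reporting_viz``)."""
        from .reporting_viz import manhattan_plot

        return manhattan_plot(self.results, spec, alpha=self._alpha,
                              m_tested=self.m_tested, **kwargs)


def run_gwas(
    regions,
    states: CnvrStateMatrix,
    phenos: PhenotypeTable,
    cfg: AssociationConfig,
) -> CnvrGwasResults:
    """One regression per region; functional wrapper over :class:`CnvrGwas`.

    ``regions`` is accepted for interface symmetry with the detection step;
    the state matrix already carries the region objects.
    """
    del regions  # carried by the state matrix
    return CnvrGwas(states, phenos, cfg).fit()


# ---------------------------------------------------------------------------
# Combined SNP + CNVR analysis
# ---------------------------------------------------------------------------


def run_combined_snp_cnvr(
    regions,
    states: CnvrStateMatrix,
    genotypes: GenotypeTable,
    phenos: PhenotypeTable,
    cfg: AssociationConfig,
    snp_map: Sequence[SnpMarker],
):
    """Joint SNP-dose + region-state model for every SNP inside each region.

    For each region and each mapped SNP within its span the model
    ``y ~ intercept + dose + state + covariates`` is fitted; the cumulative
    SNP+CNV effect is judged by a joint F-test of the (dose, state) pair
    against the covariate-only model.  Bonferroni ``M`` is the number of
    (region, SNP) models fitted.  Returns ``(results, skipped)``.
    """
    eligible = set(apply_filters(phenos, cfg.filters))
    subjects = [
        s for s in states.subject_ids if s in eligible and s in set(genotypes.subject_ids)
    ]
    if not subjects:
        raise InsufficientDataError("no subjects shared by states, phenotypes and genotypes")
    by_chrom: dict = {}
    for m in snp_map:
        by_chrom.setdefault(m.chromosome, []).append(m)
    sub = phenos.frame.loc[subjects]
    y_all = sub[_require_column(phenos, cfg.phenotype)].to_numpy(dtype=float)
    cov_all = (
        np.column_stack([sub[c].to_numpy(dtype=float) for c in cfg.covariates])
        if cfg.covariates
        else np.empty((len(subjects), 0))
    )
    geno = genotypes.frame[subjects]

    results: list[CombinedAssociationResult] = []
    skipped: list[tuple[str, str]] = []
    for region, srow in zip(states.regions, states.frame[subjects].to_numpy(dtype=float)):
        markers = [
            m
            for m in by_chrom.get(region.chromosome, [])
            if region.start_pos <= m.position <= region.end_pos and m.marker_id in geno.index
        ]
        if not markers:
            skipped.append((region.region_id, "no genotyped SNPs in span"))
            continue
        for m in markers:
            dose = geno.loc[m.marker_id].to_numpy(dtype=float)
            mask = ~np.isnan(y_all) & ~np.isnan(dose) & ~np.isnan(srow)
            if cov_all.shape[1]:
                mask &= ~np.isnan(cov_all).any(axis=1)
            yv, dv, sv, cv = y_all[mask], dose[mask], srow[mask], cov_all[mask]
            n = len(yv)
            if dv.size == 0 or dv.min() == dv.max():
                skipped.append((f"{region.region_id}/{m.marker_id}", "monomorphic SNP"))
                continue
            include_state = sv.min() != sv.max()
            if not include_state:
                warnings.warn(
                    f"{region.region_id}: state constant within region; "
                    f"model for {m.marker_id} reduces to SNP-only",
                    UserWarning,
                    stacklevel=2,
                )
            terms = [dv, sv] if include_state else [dv]
            X_full = np.column_stack([np.ones(n), *terms, cv])
            X_red = np.column_stack([np.ones(n), cv])
            if n <= X_full.shape[1]:
                skipped.append(
                    (f"{region.region_id}/{m.marker_id}", "insufficient observations")
                )
                continue
            names = ("intercept", "dose", "state", *cfg.covariates) if include_state else (
                "intercept", "dose", *cfg.covariates)
            try:
                full = fit_ols(X_full, yv, columns=names)
                red = fit_ols(X_red, yv, columns=("intercept", *cfg.covariates))
            except CollinearityError as exc:
                skipped.append((f"{region.region_id}/{m.marker_id}", f"collinear: {exc}"))
                continue
            q = len(terms)
            if full.rss <= 0:
                f_stat, f_p = math.inf, 0.0
            else:
                f_stat = ((red.rss - full.rss) / q) / (full.rss / full.df_resid)
                f_p = float(stats.f.sf(f_stat, q, full.df_resid))
            results.append(
                CombinedAssociationResult(
                    region_id=region.region_id,
                    marker_id=m.marker_id,
                    chromosome=region.chromosome,
                    position=m.position,
                    n=n,
                    df=full.df_resid,
                    snp_beta=float(full.params[1]),
                    snp_se=float(full.bse[1]),
                    snp_p=t_test_pvalue(float(full.params[1]), float(full.bse[1]),
                                        full.df_resid),
                    state_beta=float(full.params[2]) if include_state else None,
                    state_se=float(full.bse[2]) if include_state else None,
                    state_p=t_test_pvalue(float(full.params[2]), float(full.bse[2]),
                                          full.df_resid) if include_state else None,
                    f_stat=float(f_stat),
                    f_df=q,
                    f_p=f_p,
                )
            )
    if not results:
        raise InsufficientDataError("no testable (region, SNP) models")
    m_models = len(results)
    thr = bonferroni_threshold(cfg.alpha, m_models)
    for r in results:
        r.significant = r.f_p < thr
    return results, skipped
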
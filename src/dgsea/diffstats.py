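"""Per-gene differential-expression and severity-correlation statistics.

The built-in differential test is a per-gene negative-binomial log-linear
Wald test (case/control contrast plus age and gender covariates, offset
log size factor).  It is intentionally plain — method-of-moments dispersion
refined by a profile-likelihood step, no outlier handling, no shrinkage —
because everything downstream only needs a well-calibrated Wald z per gene;
externally computed tables (e.g. from DESeq2) enter through
:func:`import_stats`.

Severity association is a per-gene linear model of log2-normalised
expression on the motor score (TMS) with the same covariates, using t-tail
directional p-values.

Every table produced here satisfies p_up + p_down = 1 and
p_two = 2*min(p_up, p_down), with p floored at 1e-300 before the chi-square
conversion used as enrichment weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from .containers import CountMatrix, stats_from_z, validate_stats

__all__ = [
    "size_factors",
    "differential_stats",
    "severity_stats",
    "import_stats",
    "NegativeBinomialDE",
    "SeverityRegression",
    "DEResults",
]


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, renormalised to geometric mean 1.

    The per-gene reference is the geometric mean across samples, computed
    over genes with no zero count; each sample's factor is the median of
    its count/reference ratios.  A sample with all-zero counts, or a matrix
    with no all-nonzero gene, is an error.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    values = mat.to_numpy(dtype=float)
    zero_samples = np.where(values.sum(axis=0) == 0)[0]
    if zero_samples.size:
        raise ValueError(f"sample {mat.columns[zero_samples[0]]!r} has all-zero counts")
    allpos = np.all(values > 0, axis=1)
    if not allpos.any():
        raise ValueError("no gene with nonzero counts in every sample")
    logv = np.log(values[allpos])
    ref = logv.mean(axis=1)
    factors = np.exp(np.median(logv - ref[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB Wald differential expression
# ---------------------------------------------------------------------------


def _design(meta: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(meta))]
    for cov in covariates:
        if cov == "gender":
            cols.append((meta["gender"].astype(str).str.upper() == "M").to_numpy(float))
        else:
            vals = meta[cov].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                raise ValueError(f"covariate {cov!r} has missing values")
            cols.append(vals)
    return np.column_stack(cols)


def _nb_loglik(log_alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    r = np.exp(-log_alpha)
    return -float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            + r * np.log(r / (r + mu))
            + y * np.log(np.where(y > 0, mu, 1.0) / (r + mu)) * np.where(y > 0, 1.0, 0.0)
            - np.where(y > 0, special.gammaln(y + 1), 0.0)
        )
    )


def _estimate_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments dispersion, refined by profile-likelihood search.

    MoM on Pearson-style residuals of the fitted means initialises a
    bounded maximisation of the NB log-likelihood in log-alpha with the
    means held fixed; the result is floored at 1e-8.
    """
    mom = np.sum((y - mu) ** 2 - mu) / np.sum(mu**2)
    a0 = float(np.clip(mom, 1e-8, 50.0))
    res = optimize.minimize_scalar(
        _nb_loglik,
        bounds=(np.log(1e-8), np.log(50.0)),
        args=(y, mu),
        method="bounded",
        options={"xatol": 1e-3},
    )
    alpha = float(np.exp(res.x)) if res.success else a0
    return max(alpha, 1e-8)


@dataclass
class DEResults:
    """Per-gene statistics plus the fit's bookkeeping.

    ``table`` is a GeneStatsTable (see containers.STATS_COLUMNS); genes
    whose fit failed are absent from it and listed in ``excluded`` as
    (gene, reason).
    """

    table: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)
    model_info: dict = field(default_factory=dict)

    def summary(self, top: int = 10) -> str:
        t = self.table
        lines = [
            f"{self.model_info.get('model', 'per-gene fit')}: "
            f"{len(t)} genes fit, {len(self.excluded)} excluded",
            f"  contrast/effect: {self.model_info.get('effect', '?')}",
            f"  p_two < 0.05: {(t['p_two'] < 0.05).sum()}",
            "",
            t.reindex(t["p_two"].sort_values().index).head(top).to_string(),
        ]
        return "\n".join(lines)


class NegativeBinomialDE:
    """Per-gene NB Wald differential expression with covariates.

    ``contrast`` is ``"hd_vs_control"`` (premanifest+manifest carriers vs
    controls) or ``"manifest_vs_premanifest"``.  ``fit()`` returns
    :class:`DEResults`; the ``log2fc`` column is the contrast coefficient
    converted to log2 units and ``stat`` the Wald z, whose normal tails
    give the directional p-values.
    """

    def __init__(
        self,
        counts: CountMatrix,
        contrast: str = "hd_vs_control",
        covariates=("age", "gender"),
    ) -> None:
        self.counts = counts
        self.contrast = contrast
        self.covariates = tuple(covariates)
        meta = counts.metadata
        if contrast == "hd_vs_control":
            keep = meta.index
            x = meta["group"].isin(["premanifest", "manifest"]).astype(float)
        elif contrast == "manifest_vs_premanifest":
            keep = meta.index[meta["group"].isin(["premanifest", "manifest"])]
            x = (meta.loc[keep, "group"] == "manifest").astype(float)
        else:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if x.sum() < 2 or (len(x) - x.sum()) < 2:
            raise ValueError("each contrast group needs at least 2 samples")
        self._samples = keep
        self._x = x.to_numpy()

    def fit(self) -> DEResults:
        cm = self.counts.subset_samples(self._samples)
        sf = size_factors(cm)
        offset = np.log(sf.to_numpy())
        X = np.column_stack(
            [_design(cm.metadata, self.covariates)[:, :1], self._x,
             _design(cm.metadata, self.covariates)[:, 1:]]
        )
        contrast_ix = 1
        genes, l2fc, zs, means = [], [], [], []
        excluded: list[tuple[str, str]] = []
        norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
        for gi, gene in enumerate(cm.genes):
            y = cm.counts.iloc[gi].to_numpy(dtype=float)
            if y.sum() == 0:
                excluded.append((gene, "all-zero counts"))
                continue
            try:
                pois = sm.GLM(
                    y, X, family=sm.families.Poisson(), offset=offset
                ).fit(maxiter=50)
                alpha = _estimate_dispersion(y, pois.mu)
                nb = sm.GLM(
                    y,
                    X,
                    family=sm.families.NegativeBinomial(alpha=alpha),
                    offset=offset,
                ).fit(start_params=pois.params, maxiter=50)
                beta = nb.params[contrast_ix]
                se = nb.bse[contrast_ix]
                z = beta / se if se > 0 else 0.0
            except Exception as exc:  # noqa: BLE001 - any fit failure excludes
                excluded.append((gene, f"fit failed: {exc}"))
                continue
            if not np.isfinite(z):
                excluded.append((gene, "non-finite Wald statistic"))
                continue
            genes.append(gene)
            l2fc.append(beta / np.log(2.0))
            zs.append(z)
            means.append(norm[gi].mean())
        table = stats_from_z(genes, np.array(l2fc), np.array(zs), np.array(means))
        return DEResults(
            table,
            excluded,
            {"model": "NB Wald GLM", "effect": self.contrast,
             "covariates": self.covariates, "n_samples": len(self._samples)},
        )


def differential_stats(
    counts: CountMatrix,
    contrast: str = "hd_vs_control",
    covariates=("age", "gender"),
) -> DEResults:
    """Functional wrapper around :class:`NegativeBinomialDE`."""
    return NegativeBinomialDE(counts, contrast, covariates).fit()


# ---------------------------------------------------------------------------
# severity (TMS) regression
# ---------------------------------------------------------------------------


class SeverityRegression:
    """Per-gene linear model of log2 expression on the motor score.

    Restricted to carrier samples with a non-missing TMS.  Expression is
    log2(count / size_factor + 1); the model is expression ~ tms + age +
    gender, fit by ordinary least squares for all genes at once (the design
    matrix is shared), with directional p-values from the t distribution's
    tails.  The ``log2fc`` column of the result holds the TMS slope.
    """

    def __init__(self, counts: CountMatrix, covariates=("age", "gender")) -> None:
        meta = counts.metadata
        keep = meta.index[
            meta["group"].isin(["premanifest", "manifest"]) & meta["tms"].notna()
        ]
        n_params = 2 + len(covariates)
        if len(keep) < n_params + 3:
            raise ValueError(
                f"need at least {n_params + 3} carrier samples with TMS, got {len(keep)}"
            )
        self.counts = counts.subset_samples(keep)
        self.covariates = tuple(covariates)

    def fit(self) -> DEResults:
        cm = self.counts
        sf = size_factors(cm)
        Y = np.log2(cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0).T
        tms = cm.metadata["tms"].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(tms)), tms, _design(cm.metadata, self.covariates)[:, 1:]]
        )
        n, p = X.shape
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ Y  # p x genes
        resid = Y - X @ beta
        dof = n - p
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), np.inf * np.sign(beta[1]))
        t = np.where((se == 0) & (beta[1] == 0), 0.0, t)
        table = stats_from_z(
            cm.genes, beta[1], t, (cm.counts.to_numpy(float) / sf.to_numpy()).mean(axis=1),
            tail="t", df=dof,
        )
        return DEResults(
            table,
            [],
            {"model": "OLS severity regression", "effect": "tms slope",
             "covariates": self.covariates, "n_samples": n, "df_resid": dof},
        )


def severity_stats(counts: CountMatrix, covariates=("age", "gender")) -> DEResults:
    """Functional wrapper around :class:`SeverityRegression`."""
    return SeverityRegression(counts, covariates).fit()


# ---------------------------------------------------------------------------
# external tables
# ---------------------------------------------------------------------------

DEFAULT_DIALECT = {
    "gene": "gene",
    "log2fc": "log2fc",
    "stat": "stat",
    "p_two": "p_two",
    "p_up": "p_up",
    "p_down": "p_down",
    "mean_norm_count": "mean_norm_count",
}


def import_stats(table: pd.DataFrame, dialect: dict | None = None) -> pd.DataFrame:
    """Adapt a foreign statistics table to the GeneStatsTable layout.

    ``dialect`` maps canonical names (gene, log2fc, stat, p_two, p_up,
    p_down, mean_norm_count) to the foreign column names; only gene plus at
    least one of log2fc / stat / p_two is required.  Missing directional
    p-values are reconstructed from the statistic (or fold-change) sign and
    the two-sided p: for a negative effect, p_down = p_two/2 and
    p_up = 1 - p_two/2.  Gene ids are upper-cased; duplicates are an error.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    if mapping["gene"] not in table.columns:
        raise ValueError(f"gene column {mapping['gene']!r} not found")
    present = {k for k in ("log2fc", "stat", "p_two", "p_up", "p_down", "mean_norm_count")
               if mapping[k] in table.columns}
    if not present & {"log2fc", "stat", "p_two"}:
        raise ValueError("need at least one of log2fc / stat / p_two columns")
    df = pd.DataFrame(index=table[mapping["gene"]].astype(str).str.upper().rename("gene"))
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id after normalisation: {dup!r}")
    for key in ("log2fc", "stat", "p_two", "p_up", "p_down", "mean_norm_count"):
        if key in present:
            df[key] = table[mapping[key]].to_numpy(dtype=float)
    if "stat" not in df.columns:
        df["stat"] = df["log2fc"] if "log2fc" in df.columns else 0.0
    if "log2fc" not in df.columns:
        df["log2fc"] = df["stat"]
    if "p_up" not in df.columns or "p_down" not in df.columns:
        if "p_two" not in df.columns:
            raise ValueError("cannot reconstruct directional p-values without p_two")
        sign = np.sign(df["stat"].to_numpy())
        half = df["p_two"].to_numpy() / 2.0
        df["p_up"] = np.where(sign > 0, half, np.where(sign < 0, 1.0 - half, 0.5))
        df["p_down"] = np.where(sign < 0, half, np.where(sign > 0, 1.0 - half, 0.5))
    if "p_two" not in df.columns:
        df["p_two"] = 2.0 * np.minimum(df["p_up"], df["p_down"])
    if "mean_norm_count" not in df.columns:
        df["mean_norm_count"] = np.nan
    from .enrichment import chisq_from_p

    df["p_up"] = df["p_up"].clip(1e-300, 1.0)
    df["p_down"] = df["p_down"].clip(1e-300, 1.0)
    df["p_two"] = df["p_two"].clip(1e-300, 1.0)
    df["chi2_up"] = chisq_from_p(df["p_up"].to_numpy())
    df["chi2_down"] = chisq_from_p(df["p_down"].to_numpy())
    cols = ["log2fc", "stat", "p_two", "p_up", "p_down", "chi2_up", "chi2_down",
            "mean_norm_count"]
    return validate_stats(df[cols])
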
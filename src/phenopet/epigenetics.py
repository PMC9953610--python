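"""Stratification of clinical / epigenetic covariates by phenotype.

Once phenotypes are assigned, environmental and genetic covariates — education
years, smoking history (TOBAC), depressive episodes (DEPOTHR), APOE risk
group, alcohol abuse — are summarised per phenotype: mean ± sd for numeric
variables, level counts for categorical ones. Missing values are excluded per
variable, never imputed, and the missing count is reported so that counts +
missing always equals the phenotype size.

``violin_data`` exports per-phenotype raw values plus a Gaussian kernel
density on a shared grid, ready for violin plotting with any library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StratifiedTable", "stratify", "violin_data", "silverman_bandwidth"]

#: APOE genotype -> risk level used throughout (E4/E4 homozygotes = high).
APOE_RISK_LEVELS = {
    "low": ("E2/E2", "E2/E3", "E3/E3"),
    "medium": ("E2/E4", "E3/E4"),
    "high": ("E4/E4",),
}


@dataclass
class StratifiedTable:
    """Per-phenotype summary of a single covariate."""

    variable: str
    kind: str  # "numeric" | "categorical"
    phenotypes: list
    n_per_phenotype: dict  # phenotype -> total subjects
    missing: dict  # phenotype -> missing count
    means: dict | None = None  # numeric: phenotype -> mean
    sds: dict | None = None
    counts: pd.DataFrame | None = None  # categorical: levels x phenotypes
    chi2_p: float | None = None  # only when chi_square is requested

    def to_frame(self) -> pd.DataFrame:
        """Publication-table layout: one row per parameter, phenotype columns."""
        if self.kind == "numeric":
            rows = {
                "mean ± std": {
                    p: f"{self.means[p]:.3f} ± {self.sds[p]:.3f}" for p in self.phenotypes
                }
            }
        else:
            rows = {lvl: self.counts.loc[lvl].to_dict() for lvl in self.counts.index}
        rows["missing"] = {p: self.missing[p] for p in self.phenotypes}
        df = pd.DataFrame(rows).T
        df.index.name = self.variable
        return df


def _check_alignment(cohort: pd.DataFrame, phenotype_labels) -> np.ndarray:
    labels = np.asarray(phenotype_labels)
    if len(labels) != len(cohort):
        raise ValueError(
            f"{len(labels)} phenotype labels for {len(cohort)} cohort rows"
        )
    return labels


def stratify(
    cohort: pd.DataFrame, phenotype_labels, variables, chi_square: bool = False
) -> list[StratifiedTable]:
    """Summarise ``variables`` of the cohort within each phenotype.

    Numeric columns give mean ± sd (sample sd, ddof=1) over non-missing
    values; categorical columns give per-level counts. Unknown variables are
    rejected by name. The result is invariant to the row order of the cohort.
    ``chi_square`` optionally attaches a contingency-table chi-square p-value
    to each categorical variable (off by default: the reference tables report
    counts only).
    """
    labels = _check_alignment(cohort, phenotype_labels)
    phens = sorted(pd.unique(labels))
    out = []
    for var in variables:
        if var not in cohort.columns:
            raise KeyError(f"unknown variable {var!r}")
        col = cohort[var]
        numeric = pd.api.types.is_numeric_dtype(col)
        n_per = {p: int((labels == p).sum()) for p in phens}
        missing = {p: int(col[labels == p].isna().sum()) for p in phens}
        if numeric:
            means, sds = {}, {}
            for p in phens:
                vals = col[labels == p].dropna().to_numpy(dtype=float)
                means[p] = float(vals.mean()) if len(vals) else float("nan")
                sds[p] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
            out.append(
                StratifiedTable(
                    variable=var, kind="numeric", phenotypes=phens,
                    n_per_phenotype=n_per, missing=missing, means=means, sds=sds,
                )
            )
        else:
            levels = sorted(col.dropna().unique())
            counts = pd.DataFrame(
                {
                    p: [int((col[labels == p] == lvl).sum()) for lvl in levels]
                    for p in phens
                },
                index=pd.Index(levels, name="level"),
            )
            chi2_p = None
            if chi_square:
                from scipy.stats import chi2_contingency

                table = counts.to_numpy()
                table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
                if table.shape[0] >= 2 and table.shape[1] >= 2:
                    chi2_p = float(chi2_contingency(table).pvalue)
            out.append(
                StratifiedTable(
                    variable=var, kind="categorical", phenotypes=phens,
                    n_per_phenotype=n_per, missing=missing, counts=counts,
                    chi2_p=chi2_p,
                )
            )
    return out


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, h = 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("bandwidth needs at least 2 values")
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        raise ValueError("cannot form a density from constant values")
    return float(0.9 * spread * n ** (-1 / 5))


def violin_data(
    cohort: pd.DataFrame,
    phenotype_labels,
    variable: str,
    grid_size: int = 201,
) -> dict:
    """Per-phenotype raw values + Gaussian kernel density for violin plots.

    The density for each phenotype is the mean of Gaussian kernels centred at
    its non-missing values, bandwidth by Silverman's rule, evaluated on a
    shared grid spanning all groups ± 3 bandwidths. Returns a dict
    ``{phenotype: {"values", "grid", "density", "bandwidth"}}``; each density
    integrates to ~1 over its grid.
    """
    labels = _check_alignment(cohort, phenotype_labels)
    if variable not in cohort.columns:
        raise KeyError(f"unknown variable {variable!r}")
    col = cohort[variable]
    if not pd.api.types.is_numeric_dtype(col):
        raise TypeError(
            f"variable {variable!r} is categorical; use stratify for counts"
        )
    phens = sorted(pd.unique(labels))
    groups = {
        p: col[labels == p].dropna().to_numpy(dtype=float) for p in phens
    }
    bandwidths = {p: silverman_bandwidth(v) for p, v in groups.items() if len(v) >= 2}
    if not bandwidths:
        raise ValueError("no phenotype has enough values for a density")
    all_vals = np.concatenate([v for v in groups.values() if len(v)])
    pad = 3 * max(bandwidths.values())
    grid = np.linspace(all_vals.min() - pad, all_vals.max() + pad, grid_size)
    out = {}
    for p, vals in groups.items():
        if p in bandwidths:
            h = bandwidths[p]
            z = (grid[:, None] - vals[None, :]) / h
            density = np.exp(-0.5 * z**2).sum(axis=1) / (
                len(vals) * h * np.sqrt(2 * np.pi)
            )
        else:
            h, density = float("nan"), np.full(grid_size, np.nan)
        out[p] = {"values": vals, "grid": grid, "density": density, "bandwidth": h}
    return out
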
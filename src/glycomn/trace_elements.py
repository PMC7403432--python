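"""ICP-MS trace-element panel: MDL filtering and genotype statistics.

A serum panel of 23 trace elements (μg/L) is screened with the standard
EPA-style method detection limit: MDL = t(0.99, n-1) x SD of n replicate
low-level QC runs (n = 7 by design, multiplier 3.143).  An element enters
the genotype analysis only when its mean concentration across all samples
exceeds its MDL — measurements below the MDL are indistinguishable from
background.  Values below the MDL are retained as measured by default
(censoring at the MDL is available but off), and group comparisons reuse
the shared ANOVA + pairwise-Welch machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glycome_stats import group_compare

__all__ = [
    "ELEMENTS",
    "ElementPanel",
    "compute_mdl",
    "filter_elements",
    "element_genotype_stats",
    "percent_reduction",
    "covariate_regression",
]

#: the 23 measured element symbols
ELEMENTS = (
    "As", "Ba", "Be", "Cd", "Co", "Cr", "Cs", "Cu", "Hg", "Mn", "Mo", "Ni",
    "Pb", "Pt", "Sb", "Se", "Sn", "Te", "Tl", "U", "V", "W", "Zn",
)


@dataclass
class ElementPanel:
    """Samples x 23 element concentration matrix with per-element MDLs."""

    concentrations: pd.DataFrame  # index: sample_id, columns: ELEMENTS, μg/L
    mdl: pd.Series  # element -> MDL, μg/L

    def __post_init__(self):
        cols = tuple(self.concentrations.columns)
        if sorted(cols) != sorted(ELEMENTS):
            raise ValueError(f"panel must cover exactly the 23 elements, got {len(cols)}")
        if (self.concentrations.to_numpy() < 0).any():
            raise ValueError("concentrations must be non-negative")
        self.mdl = self.mdl.reindex(list(cols))
        if self.mdl.isna().any() or (self.mdl <= 0).any():
            raise ValueError("every element needs a positive MDL")

    def censored(self) -> pd.DataFrame:
        """Concentrations with sub-MDL values set to MDL/2 (optional view)."""
        c = self.concentrations.copy()
        for el in c.columns:
            below = c[el] < self.mdl[el]
            c.loc[below, el] = self.mdl[el] / 2.0
        return c


def compute_mdl(qc_runs: pd.DataFrame, confidence: float = 0.99) -> pd.Series:
    """Method detection limit per element from replicate low-level QC runs.

    ``qc_runs`` is an element x replicate table (7 replicates by design).
    MDL = t(confidence, n-1) x SD(replicates), the single-sided Student-t
    convention; the multiplier is computed from the t distribution
    (3.143 at n = 7).
    """
    n = qc_runs.shape[1]
    if n < 2:
        raise ValueError("MDL requires at least 2 replicate QC runs")
    multiplier = float(stats.t.ppf(confidence, n - 1))
    sd = qc_runs.std(axis=1, ddof=1)
    return multiplier * sd


def filter_elements(panel: ElementPanel):
    """Partition elements by the mean-above-MDL inclusion rule.

    An element is included iff its mean concentration across all samples is
    strictly greater than its MDL.  Returns ``(included, excluded, audit)``
    where ``audit`` is a per-element table with mean, MDL and the flag.
    """
    means = panel.concentrations.mean(axis=0)
    included = [el for el in panel.concentrations.columns if means[el] > panel.mdl[el]]
    excluded = [el for el in panel.concentrations.columns if el not in included]
    audit = pd.DataFrame(
        {
            "mean_ugL": means,
            "mdl_ugL": panel.mdl,
            "included": [el in included for el in means.index],
        }
    )
    audit.index.name = "element"
    return included, excluded, audit


def element_genotype_stats(
    panel: ElementPanel,
    genotypes: pd.Series,
    reference: str = "CC",
    elements: list | None = None,
) -> pd.DataFrame:
    """ANOVA + pairwise Welch t per included element (shared implementation)."""
    if elements is None:
        elements, _, _ = filter_elements(panel)
    values = panel.concentrations[elements]
    return group_compare(values, genotypes, reference=reference)


def percent_reduction(mean_ref: float, mean_alt: float) -> float:
    """Percent reduction of ``mean_alt`` relative to ``mean_ref``.

    Summaries round this to integer percent (e.g. 0.814 vs 0.669 μg/L →
    17.8 → 18%).
    """
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_ref - mean_alt) / mean_ref


def covariate_regression(
    panel: ElementPanel,
    metadata: pd.DataFrame,
    element: str,
    covariate: str,
):
    """Simple linear regression of an element concentration on a covariate.

    Ordinary least squares with a two-sided t-test on the slope; returns
    ``(slope, intercept, p_value)``.  Requires >= 3 samples and a
    non-constant covariate.
    """
    y = panel.concentrations[element]
    x = metadata.loc[y.index, covariate].astype(float)
    if len(x) < 3:
        raise ValueError("regression requires at least 3 samples")
    if np.ptp(x.to_numpy()) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    res = stats.linregress(x.to_numpy(), y.to_numpy())
    return float(res.slope), float(res.intercept), float(res.pvalue)
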
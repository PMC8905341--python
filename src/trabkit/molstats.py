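"""qPCR expression ratios, viability quantification and statistics.

qPCR: reaction efficiency E is recovered per experiment from a template
dilution series (Ct vs log10 relative template; E = 10^(-1/slope)), and
relative expression follows the efficiency-corrected ratio

    ratio = E_target^dCt_target / geo-mean_ref( E_ref^dCt_ref ),

with dCt = mean Ct(control) - mean Ct(treated), so upregulation gives
ratio > 1. Reference genes (EEF2, HPRT1 in the assay this package targets)
are combined by geometric mean.

Viability: Bradford protein from a BSA standard curve (linear regression,
inverted for samples, extrapolation flagged), and MTT formazan absorbance
divided by total protein (relative absorbance).

Statistics: paired and Welch two-sided t-tests, Holm-Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

REFERENCE_GENES = ("EEF2", "HPRT1")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def qpcr_efficiency(dilution_cts: np.ndarray, dilution_factors: np.ndarray) -> float:
    """Reaction efficiency from a dilution series.

    ``dilution_factors`` are relative template amounts (e.g. 1/5, 1/25, ...).
    Least-squares slope of Ct vs log10(template); E = 10^(-1/slope).
    """
    cts = np.asarray(dilution_cts, float)
    dil = np.asarray(dilution_factors, float)
    if cts.size < 3:
        raise ValueError("need >= 3 dilution points")
    res = stats.linregress(np.log10(dil), cts)
    if res.slope >= 0:
        raise ValueError(
            f"non-monotone dilution series (slope {res.slope:.3f} >= 0); "
            "Ct must increase with dilution"
        )
    return float(10.0 ** (-1.0 / res.slope))


def _mean_ct(table: pd.DataFrame, gene: str, group: str) -> float:
    rows = table[(table["gene"] == gene) & (table["group"] == group)]
    if rows.empty:
        raise ValueError(f"no Ct rows for gene {gene!r}, group {group!r}")
    reps = rows[[c for c in rows.columns if c.startswith("ct_")]].to_numpy(float)
    return float(reps.mean(axis=1).mean())   # triplicates averaged per sample first


def efficiency_from_table(table: pd.DataFrame, gene: str) -> float:
    """Efficiency of one gene from its dilution-series rows in a Ct table."""
    rows = table[(table["gene"] == gene) & (table["group"] == "dilution")]
    if rows.empty:
        raise ValueError(f"no dilution series for gene {gene!r}")
    reps = rows[[c for c in rows.columns if c.startswith("ct_")]].to_numpy(float)
    return qpcr_efficiency(reps.mean(axis=1), rows["dilution"].to_numpy(float))


def expression_ratio(table: pd.DataFrame, target_gene: str,
                     reference_genes: tuple[str, ...] = REFERENCE_GENES,
                     efficiencies: dict[str, float] | None = None,
                     control_group: str = "fresh",
                     treated_group: str = "cultured") -> dict:
    """Efficiency-corrected expression ratio of treated vs control.

    Triplicate Cts are averaged per sample, then per group; missing reference
    measurements raise. Returns a dict with the ratio, per-gene dCt and the
    efficiencies used (estimated from the table's dilution series when not
    supplied).
    """
    genes = (target_gene,) + tuple(reference_genes)
    eff = dict(efficiencies or {})
    for g in genes:
        if g not in eff:
            eff[g] = efficiency_from_table(table, g)
    dct = {g: _mean_ct(table, g, control_group) - _mean_ct(table, g, treated_group)
           for g in genes}
    target_term = eff[target_gene] ** dct[target_gene]
    ref_terms = [eff[g] ** dct[g] for g in reference_genes]
    ref_geo = float(np.exp(np.mean(np.log(ref_terms))))
    return dict(
        gene=target_gene, ratio=target_term / ref_geo,
        dct=dct, efficiencies={g: eff[g] for g in genes},
        reference_genes=tuple(reference_genes),
        sign_convention="dCt = Ct(control) - Ct(treated); upregulation > 1",
    )


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------

@dataclass
class BradfordFit:
    slope: float        # absorbance per (mg/ml)
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def invert(self, absorbance: float) -> tuple[float, bool]:
        """Concentration for an absorbance; flags extrapolation."""
        conc = (absorbance - self.intercept) / self.slope
        lo, hi = self.conc_range
        extrapolated = not (lo <= conc <= hi)
        return float(conc), extrapolated


def bradford_fit(standard_conc: np.ndarray, standard_abs: np.ndarray) -> BradfordFit:
    conc = np.asarray(standard_conc, float)
    absr = np.asarray(standard_abs, float)
    if conc.size < 3:
        raise ValueError("need >= 3 standards")
    if np.allclose(conc, conc[0]):
        raise ValueError("singular standard curve (constant concentration)")
    res = stats.linregress(conc, absr)
    return BradfordFit(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2),
                       conc_range=(float(conc.min()), float(conc.max())))


def bradford_quantify(standard_conc, standard_abs, sample_abs) -> pd.DataFrame:
    """Protein concentrations of samples via the BSA standard curve."""
    fit = bradford_fit(standard_conc, standard_abs)
    rows = []
    for a in np.atleast_1d(np.asarray(sample_abs, float)):
        conc, extra = fit.invert(a)
        rows.append(dict(absorbance=a, protein=conc, extrapolated=extra,
                         r_squared=fit.r_squared))
    return pd.DataFrame(rows)


def mtt_relative_absorbance(a595: float, protein: float) -> float:
    """Formazan absorbance per unit protein (viability indicator)."""
    if protein <= 0:
        raise ValueError("protein must be > 0")
    return a595 / protein


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def paired_t(x, y) -> float:
    """Two-sided paired t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired_t needs equal-length samples of size >= 2")
    d = x - y
    if np.allclose(d.std(), 0):
        if np.allclose(d.mean(), 0):
            log.info("paired_t: zero variance and equal means; p = 1 by convention")
            return 1.0
        return 0.0
    return float(stats.ttest_rel(x, y).pvalue)


def welch_t(x, y) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs samples of size >= 2")
    if np.allclose(x.std(), 0) and np.allclose(y.std(), 0):
        if np.allclose(x.mean(), y.mean()):
            log.info("welch_t: zero variance and equal means; p = 1 by convention")
            return 1.0
        return 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in the input order.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the ascending
    ordering of the raw p-values.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("need >= 1 p-value")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
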
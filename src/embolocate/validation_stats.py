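"""Agreement tables and summary statistics for workflow validation.

Two raters (e.g. the automated workflow and a human reading histology)
each allocate the same spheres to ontology structures.  Agreement is
scored level by level: at level k two allocations agree when their level-k
ancestors match; a sphere whose reference structure's branch ends above k
is "not at this level" and still counts toward the *sum of agreement*
(it was correctly allocated as deep as its branch goes).
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ontology_assignment import AtlasOntology, NOT_AT_LEVEL


class ZeroVarianceError(ValueError):
    """A statistic is undefined because an input has no variance."""


def round_half_up(value: float, decimals: int = 1) -> float:
    """Half-up decimal rounding, as printed tables round."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent_agreement(agree: int, total: int) -> float:
    """100 * agree/total, half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * agree / total, 1)


def agreement_by_level(
    reference: Mapping,
    test: Mapping,
    ontology: AtlasOntology,
    levels: Sequence[int] = tuple(range(1, 13)),
    sparse_levels: Sequence[int] = (11, 12),
) -> pd.DataFrame:
    """Level-wise agreement between two per-sphere structure allocations.

    ``reference`` and ``test`` map sphere id -> ontology id.  At level k a
    sphere is *agreement* when both allocations have (matching) level-k
    ancestors.  When the reference structure's branch ends above k, the
    sphere is *not at this level* provided it was correctly allocated at
    its own terminal level (otherwise it stays a disagreement — a sphere
    cannot be "correctly allocated up to" a level it was misallocated at).
    Everything else is *disagreement*.  Sum of agreement = agreement +
    not-at-level, and is non-increasing with depth.  Percentages are
    half-up to one decimal.  Levels listed in ``sparse_levels`` are
    computed but flagged, since few structures reach them.
    """
    if set(reference) != set(test):
        raise ValueError("reference and test allocations cover different sphere ids")
    rows = []
    total = len(reference)
    for k in levels:
        agree = nal = disagree = 0
        for sid in reference:
            ref_level = ontology.level(reference[sid])
            kk = min(k, ref_level)
            ref_anc = ontology.ancestor_at_level(reference[sid], kk)
            test_anc = ontology.ancestor_at_level(test[sid], kk)
            matched = test_anc != NOT_AT_LEVEL and test_anc == ref_anc
            if ref_level < k:
                if matched:
                    nal += 1
                else:
                    disagree += 1
            elif matched:
                agree += 1
            else:
                disagree += 1
        soa = agree + nal
        rows.append(
            {
                "level": k,
                "agreement": agree,
                "not_at_level": nal,
                "sum_of_agreement": soa,
                "disagreement": disagree,
                "total": total,
                "agreement_pct": percent_agreement(agree, total),
                "not_at_level_pct": percent_agreement(nal, total),
                "sum_of_agreement_pct": percent_agreement(soa, total),
                "disagreement_pct": percent_agreement(disagree, total),
                "sparse": k in sparse_levels,
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> tuple[float, float, float]:
    """Product-moment correlation: (r, r^2, two-sided p with n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def t_test(a, b, mode: str = "paired", welch: bool = False, alpha: float = 0.05):
    """Two-sided t test: (t, df, p, significant at ``alpha``).

    ``paired`` runs the test on the within-pair differences (df = n-1);
    ``independent`` uses the pooled-variance Student test (df = n1+n2-2)
    unless ``welch`` is requested.  Identical paired samples yield t = 0,
    p = 1; constant nonzero differences have no variance and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "paired":
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        d = a - b
        if np.std(d, ddof=1) == 0:
            if np.all(d == 0):
                return 0.0, len(d) - 1, 1.0, False
            raise ZeroVarianceError("constant nonzero paired differences")
        res = stats.ttest_rel(a, b)
        t, p, df = float(res.statistic), float(res.pvalue), len(a) - 1
    elif mode == "independent":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each sample needs at least 2 observations")
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                df = len(a) + len(b) - 2
                return 0.0, df, 1.0, False
            raise ZeroVarianceError("both samples constant with different means")
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df) if welch else len(a) + len(b) - 2
    else:
        raise ValueError(f"unknown t-test mode {mode!r}")
    return t, df, p, p < alpha


def loss_percentage(blockface_count: int, histology_count: int) -> float:
    """Percent of spheres seen in block-face images but lost from histology."""
    if blockface_count <= 0:
        raise ValueError("blockface count must be positive")
    if histology_count > blockface_count:
        warnings.warn("histology count exceeds block-face count; negative loss")
    return 100.0 * (blockface_count - histology_count) / blockface_count
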
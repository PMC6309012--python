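"""Population-differentiation statistics and cluster-number diagnostics.

Nei's G_ST partitions expected heterozygosity into within- and
between-population components; Hedrick's G'_ST rescales it by its maximum
attainable value given the within-population diversity, making values
comparable across loci of different polymorphism.  The Evanno ΔK statistic
post-processes an externally produced table of clustering log-likelihoods
(e.g. STRUCTURE runs across K) into the second-order rate of change that
peaks at the best-supported number of clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sfs import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DifferentiationResult:
    """Per-locus and multilocus G_ST / G'_ST.

    ``per_locus`` columns: locus_id, H_S, H_T, G_ST, G_prime_ST.
    Multilocus values follow Nei: (mean H_T - mean H_S) / mean H_T, with the
    Hedrick standardization applied to the multilocus values using mean H_S.
    """

    per_locus: pd.DataFrame
    multilocus_gst: float
    multilocus_gst_prime: float
    k: int
    n_skipped: int


def _hedrick(gst: float, h_s: float, k: int) -> float:
    if h_s >= 1.0:
        return 0.0
    return gst * (k - 1 + h_s) / ((k - 1) * (1.0 - h_s))


def differentiation(
    gm: GenotypeMatrix,
    populations: tuple[str, ...] | None = None,
    weighted: bool = False,
) -> DifferentiationResult:
    """Nei's G_ST and Hedrick's G'_ST from biallelic SNP genotypes.

    Allele frequencies are averaged over populations without sample-size
    weights by default (Nei's original formulation); ``weighted=True``
    weights by the number of called chromosomes.  Loci with a population
    entirely missing are skipped (count logged and returned).
    """
    if populations is None:
        seen: list[str] = []
        for ind in gm.individuals:
            p = gm.pop_of[ind]
            if p not in seen:
                seen.append(p)
        populations = tuple(seen)
    k = len(populations)
    if k < 2:
        raise ValueError("differentiation requires at least two populations")
    cols = [gm.columns_for(p) for p in populations]

    rows = []
    n_skipped = 0
    for s in range(gm.n_sites):
        freqs, ns = [], []
        ok = True
        for c in cols:
            calls = gm.calls[s, c]
            called = calls[calls != MISSING]
            if called.size == 0:
                ok = False
                break
            freqs.append(called.sum() / (2.0 * called.size))
            ns.append(2 * called.size)
        if not ok:
            n_skipped += 1
            continue
        freqs = np.asarray(freqs)
        w = np.asarray(ns, float) / sum(ns) if weighted else np.full(k, 1.0 / k)
        h_s = float((w * 2.0 * freqs * (1.0 - freqs)).sum())
        p_bar = float((w * freqs).sum())
        h_t = 2.0 * p_bar * (1.0 - p_bar)
        gst = 0.0 if h_t == 0 else (h_t - h_s) / h_t
        rows.append(
            {
                "locus_id": gm.sites[s].locus_id,
                "H_S": h_s,
                "H_T": h_t,
                "G_ST": gst,
                "G_prime_ST": _hedrick(gst, h_s, k),
            }
        )
    if n_skipped:
        logger.info("skipped %d loci with a population entirely missing", n_skipped)
    if not rows:
        raise ValueError("no usable loci")
    per_locus = pd.DataFrame(rows)
    mean_hs = float(per_locus["H_S"].mean())
    mean_ht = float(per_locus["H_T"].mean())
    ml_gst = 0.0 if mean_ht == 0 else (mean_ht - mean_hs) / mean_ht
    return DifferentiationResult(
        per_locus, ml_gst, _hedrick(ml_gst, mean_hs, k), k, n_skipped
    )


def evanno_delta_k(table: pd.DataFrame) -> pd.DataFrame:
    """Evanno's ΔK from a (K, replicate, loglik) table.

    ΔK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K), defined for
    interior K only; requires consecutive K values and >=2 replicates per K.
    """
    required = {"K", "loglik"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    grouped = table.groupby("K")["loglik"]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    counts = grouped.count()
    ks = sorted(means.index)
    if len(ks) < 3:
        return pd.DataFrame(columns=["K", "delta_K"])
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >=2 replicates per K; too few at K={bad}")
    rows = []
    for k in ks[1:-1]:
        sd = sds[k]
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"zero replicate standard deviation at K={k}")
        rows.append(
            {"K": k, "delta_K": abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sd}
        )
    return pd.DataFrame(rows)
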
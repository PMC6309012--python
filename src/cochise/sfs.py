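"""Unfolded joint site-frequency spectra from SNP genotypes.

This module turns diploid SNP calls for three populations (Sonoran,
Chihuahuan, and the *carneus* outgroup) into an unfolded joint SFS: sites
are polarized against a designated outgroup, and each site's derived-allele
counts are projected down to a common haploid sample size by hypergeometric
averaging, which absorbs missing data.  The SFS is serialized in the plain
three-line text dialect used by ∂a∂i-style tools (dimension line, flattened
counts, mask line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP site."""

    chrom: str
    pos: int  # 1-based, per VCF convention
    locus_id: str
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Diploid SNP calls (alt-allele dosage 0/1/2, MISSING=-1) for labelled individuals.

    ``calls`` has shape (n_sites, n_individuals); ``pop_of`` maps every
    individual ID to a population label (e.g. SON, CHI, CAR).
    """

    sites: list[SiteRecord]
    calls: np.ndarray
    individuals: list[str]
    pop_of: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.individuals)} individuals"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        for ind in self.individuals:
            if ind not in self.pop_of:
                raise KeyError(f"individual {ind!r} has no population label")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def columns_for(self, population: str) -> np.ndarray:
        """Indices of the individuals belonging to ``population``."""
        return np.array(
            [i for i, ind in enumerate(self.individuals) if self.pop_of[ind] == population],
            dtype=int,
        )


@dataclass
class JointSFS:
    """Unfolded joint SFS over up to three populations.

    ``counts[i, j, k]`` is the (possibly fractional, after projection) number
    of sites with i/j/k derived copies in the respective populations.
    ``mask`` is True where an entry is excluded from likelihood sums; the two
    monomorphic corners are always masked.
    """

    counts: np.ndarray
    sample_sizes: tuple[int, ...]
    mask: np.ndarray
    polarized: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected_shape = tuple(n + 1 for n in self.sample_sizes)
        if self.counts.shape != expected_shape:
            raise ValueError(
                f"counts shape {self.counts.shape} != {expected_shape} implied by sample sizes"
            )
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.counts.shape:
            raise ValueError("mask shape must match counts shape")
        if (self.counts < 0).any():
            raise ValueError("SFS counts must be non-negative")

    @classmethod
    def zeros(cls, sample_sizes: tuple[int, ...]) -> "JointSFS":
        shape = tuple(n + 1 for n in sample_sizes)
        sfs = cls(np.zeros(shape), tuple(sample_sizes), np.zeros(shape, dtype=bool))
        sfs.mask_corners()
        return sfs

    def mask_corners(self) -> None:
        """Mask the two monomorphic corners (no derived / all derived)."""
        self.mask[tuple(0 for _ in self.sample_sizes)] = True
        self.mask[tuple(n for n in self.sample_sizes)] = True

    def unmasked_sum(self) -> float:
        return float(self.counts[~self.mask].sum())

    def total_mass(self) -> float:
        return float(self.counts.sum())


@dataclass
class PolarizedSites:
    """Per-site derived-allele counts after outgroup polarization.

    ``derived[s, p]`` and ``n_chrom[s, p]`` give the derived copies and the
    number of successfully genotyped chromosomes for site s in population p
    (order given by ``populations``).
    """

    derived: np.ndarray
    n_chrom: np.ndarray
    populations: tuple[str, ...]
    n_dropped: int


def read_popmap(path) -> dict[str, str]:
    """Read a two-column (sample, population) whitespace/tab-delimited map."""
    pop_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            pop_of[parts[0]] = parts[1]
    return pop_of


def read_genotypes(vcf_path, pop_of: dict[str, str]) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a GenotypeMatrix.

    Multi-allelic records are skipped (count recorded in ``meta``).  The VCF
    ID field, when present, is used as the locus identifier (one ddRAD locus
    may carry several SNPs); otherwise the contig name is used.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_of:
            raise KeyError(f"sample {s!r} in VCF is absent from the population map")

    sites: list[SiteRecord] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        if gts is None:
            raise ValueError(f"record {var.CHROM}:{var.POS} has no GT field")
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            row[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        locus = var.ID if var.ID not in (None, ".", "") else var.CHROM
        sites.append(SiteRecord(var.CHROM, var.POS, locus, var.REF, var.ALT[0]))
        rows.append(row)
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    calls = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(
        sites, calls, samples, dict(pop_of), meta={"skipped_multiallelic": n_multi}
    )


def thin_to_unlinked(gm: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Keep exactly one (seeded-uniform) SNP per locus_id."""
    rng = np.random.default_rng(seed)
    by_locus: dict[str, list[int]] = {}
    for i, site in enumerate(gm.sites):
        by_locus.setdefault(site.locus_id, []).append(i)
    keep = sorted(int(rng.choice(idx)) for idx in by_locus.values())
    meta = dict(gm.meta)
    meta["thin_seed"] = seed
    return GenotypeMatrix(
        [gm.sites[i] for i in keep], gm.calls[keep], list(gm.individuals), dict(gm.pop_of), meta
    )


def polarize_sites(
    gm: GenotypeMatrix,
    outgroup_ids: list[str],
    populations: tuple[str, ...] | None = None,
) -> PolarizedSites:
    """Polarize sites to derived-allele counts using an outgroup consensus.

    The ancestral allele is the allele carried homozygously by every called
    outgroup individual; sites with a heterozygous, polymorphic, or entirely
    missing outgroup are dropped.  Dropped-site count is logged and recorded.
    """
    if not outgroup_ids:
        raise ValueError("at least one outgroup individual is required")
    out_cols = np.array([gm.individuals.index(o) for o in outgroup_ids], dtype=int)
    if populations is None:
        out_set = set(outgroup_ids)
        seen: list[str] = []
        for ind in gm.individuals:
            p = gm.pop_of[ind]
            if ind not in out_set and p not in seen:
                seen.append(p)
        populations = tuple(seen)
    pop_cols = [gm.columns_for(p) for p in populations]

    derived_rows, nchrom_rows = [], []
    n_dropped = 0
    for s in range(gm.n_sites):
        out_calls = gm.calls[s, out_cols]
        out_calls = out_calls[out_calls != MISSING]
        if out_calls.size == 0 or not (np.all(out_calls == 0) or np.all(out_calls == 2)):
            n_dropped += 1
            continue
        ancestral_is_ref = out_calls[0] == 0
        d_row, n_row = [], []
        for cols in pop_cols:
            calls = gm.calls[s, cols]
            called = calls[calls != MISSING]
            n = 2 * called.size
            alt = int(called.sum())
            d_row.append(alt if ancestral_is_ref else n - alt)
            n_row.append(n)
        derived_rows.append(d_row)
        nchrom_rows.append(n_row)
    if not derived_rows:
        raise ValueError("no polarizable sites")
    if n_dropped:
        logger.info("dropped %d sites with ambiguous or missing outgroup", n_dropped)
    return PolarizedSites(
        np.array(derived_rows, dtype=int),
        np.array(nchrom_rows, dtype=int),
        populations,
        n_dropped,
    )


@lru_cache(maxsize=200_000)
def project_site(d: int, n: int, m: int) -> tuple[float, ...]:
    """Hypergeometric projection of d derived copies out of n chromosomes to m.

    Entry j is the probability that a uniform subsample of m chromosomes
    carries exactly j derived copies: C(d,j) C(n-d, m-j) / C(n,m).
    """
    if not 0 <= d <= n:
        raise ValueError(f"need 0 <= d <= n, got d={d}, n={n}")
    if m < 1:
        raise ValueError("target size m must be >= 1")
    j = np.arange(m + 1)
    return tuple(hypergeom.pmf(j, n, d, m))


def build_joint_sfs(pol: PolarizedSites, target_sizes: tuple[int, ...]) -> JointSFS:
    """Project per-site derived counts to ``target_sizes`` and accumulate the SFS.

    Sites with fewer observed chromosomes than the target in any population
    are dropped (projection only ever goes down).  Monomorphic corners are
    masked afterwards.
    """
    n_pops = len(pol.populations)
    if len(target_sizes) != n_pops:
        raise ValueError("target_sizes length must match number of populations")
    sfs = JointSFS.zeros(tuple(target_sizes))
    # unmask while accumulating; corners re-masked below
    sfs.mask[:] = False
    n_dropped = 0
    usable = (pol.n_chrom >= np.asarray(target_sizes)).all(axis=1)
    if not usable.any():
        raise ValueError("no site has enough observed chromosomes in every population")
    for s in np.nonzero(usable)[0]:
        vecs = [
            np.asarray(project_site(int(pol.derived[s, p]), int(pol.n_chrom[s, p]), target_sizes[p]))
            for p in range(n_pops)
        ]
        outer = vecs[0]
        for v in vecs[1:]:
            outer = np.multiply.outer(outer, v)
        sfs.counts += outer
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("dropped %d sites below the projection target size", n_dropped)
    sfs.mask_corners()
    return sfs


def write_sfs(path, sfs: JointSFS) -> None:
    """Write a JointSFS in the three-line ∂a∂i text dialect."""
    with open(path, "w") as fh:
        dims = " ".join(str(n + 1) for n in sfs.sample_sizes)
        fh.write(f"{dims} {'unfolded' if sfs.polarized else 'folded'}\n")
        fh.write(" ".join(repr(float(x)) for x in sfs.counts.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in sfs.mask.ravel()) + "\n")


def read_sfs(path) -> JointSFS:
    """Read a JointSFS from the three-line ∂a∂i text dialect."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) < 3:
        raise ValueError(f"SFS file {path} must have header, counts, and mask lines")
    header = lines[0].split()
    if header[-1] not in ("unfolded", "folded"):
        raise ValueError(f"bad SFS header: {lines[0]!r}")
    shape = tuple(int(x) for x in header[:-1])
    counts = np.array([float(x) for x in lines[1].split()])
    mask = np.array([x == "1" for x in lines[2].split()])
    if counts.size != np.prod(shape) or mask.size != counts.size:
        raise ValueError("counts/mask length does not match header dimensions")
    return JointSFS(
        counts.reshape(shape),
        tuple(n - 1 for n in shape),
        mask.reshape(shape),
        polarized=header[-1] == "unfolded",
    )
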
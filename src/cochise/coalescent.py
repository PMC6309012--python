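"""Structured-coalescent simulation for three desert demes.

Implements the six demographic histories compared for Sonoran and Chihuahuan
Northern Cardinals plus the *carneus* outgroup: pure isolation, isolation
with symmetric / asymmetric / one-way migration, and secondary contact.
Backwards in time, lineages coalesce within demes at rate C(k,2)/N (haploid
N, time in generations), migrate between the two desert demes at per-lineage
per-generation rates where the model allows it, merge into the
ancestral-desert deme at the divergence time T_D, and into the root deme at
the calibration split T_A (fixed at 2 My).

Expected joint SFS entries are computed by branch-length accumulation
(Rao-Blackwellized over mutation placement): entry (i,j,k) is the mean total
length of branches subtending exactly i/j/k sampled chromosomes per deme,
times the per-generation mutation rate.  A numba kernel does the heavy
lifting; :func:`simulate_genealogy` is an independent pure-Python reference
used for per-branch inspection and cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .sfs import MISSING, GenotypeMatrix, JointSFS, SiteRecord

# Fixed calibration constants: outgroup split (years), generation time
# (years), and mutation rate (per site per year).
T_ANCESTRAL_YEARS = 2_000_000.0
GENERATION_TIME_YEARS = 1.0
MU_PER_SITE_PER_YEAR = 2.21e-9

MODEL_IDS = ("ISO", "SYM", "ASYM", "SON2CHI", "CHI2SON", "SECCONTACT")

_BASE_PARAMS = ("N_eS", "N_eC", "N_eO", "N_eD", "N_eA", "T_D")
_FREE_PARAMS = {
    "ISO": _BASE_PARAMS,
    "SYM": _BASE_PARAMS + ("m",),
    "ASYM": _BASE_PARAMS + ("m_S", "m_C"),
    "SON2CHI": _BASE_PARAMS + ("m_S",),
    "CHI2SON": _BASE_PARAMS + ("m_C",),
    "SECCONTACT": _BASE_PARAMS + ("m_S", "m_C", "T_SC"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the six three-population demographic topologies."""

    model_id: str
    free_parameters: tuple[str, ...]
    fixed: dict = field(
        default_factory=lambda: {
            "T_A": T_ANCESTRAL_YEARS,
            "generation_time": GENERATION_TIME_YEARS,
            "mu": MU_PER_SITE_PER_YEAR,
        }
    )

    @property
    def k(self) -> int:
        """Number of free parameters (the AIC penalty count)."""
        return len(self.free_parameters)


def model_catalog() -> list[ModelSpec]:
    """The six candidate demographic models, in canonical order."""
    return [ModelSpec(mid, _FREE_PARAMS[mid]) for mid in MODEL_IDS]


def get_model(model_id: str) -> ModelSpec:
    if model_id not in _FREE_PARAMS:
        raise KeyError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")
    return ModelSpec(model_id, _FREE_PARAMS[model_id])


@dataclass
class ParameterVector:
    """Concrete demographic parameters.

    Sizes are haploid; times are in years; ``m_S`` and ``m_C`` are backward
    per-lineage per-generation migration probabilities (``m_S``: a Chihuahuan
    lineage's ancestry jumps to the Sonoran deme, i.e. forward
    Sonoran-to-Chihuahuan migration; ``m_C`` the reverse).
    """

    N_eS: float
    N_eC: float
    N_eO: float
    N_eD: float
    N_eA: float
    T_D: float
    T_SC: float = 0.0
    m_S: float = 0.0
    m_C: float = 0.0

    def validate(self) -> None:
        for name in ("N_eS", "N_eC", "N_eO", "N_eD", "N_eA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.T_D < T_ANCESTRAL_YEARS:
            raise ValueError("require 0 < T_D < T_A")
        if not 0 <= self.T_SC <= self.T_D:
            raise ValueError("require 0 <= T_SC <= T_D")
        for name in ("m_S", "m_C"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be a probability in [0, 1)")

    @classmethod
    def for_model(cls, model: ModelSpec | str, **values: float) -> "ParameterVector":
        """Build a vector from a model's free parameters; extras raise.

        For SYM the single ``m`` sets both directions.
        """
        if isinstance(model, str):
            model = get_model(model)
        extra = set(values) - set(model.free_parameters)
        if extra:
            raise ValueError(
                f"parameters {sorted(extra)} are not free in model {model.model_id}"
            )
        missing = set(model.free_parameters) - set(values)
        if missing:
            raise ValueError(f"missing parameters {sorted(missing)} for {model.model_id}")
        kwargs = {k: v for k, v in values.items() if k != "m"}
        if model.model_id == "SYM":
            kwargs["m_S"] = kwargs["m_C"] = values["m"]
        if model.model_id != "SECCONTACT":
            kwargs["T_SC"] = 0.0
        pv = cls(**kwargs)
        pv.validate()
        return pv


@dataclass(frozen=True)
class PriorSpec:
    """A one-dimensional sampling prior: log-uniform or uniform on [lower, upper]."""

    dist: str  # "log-uniform" | "uniform"
    lower: float
    upper: float
    soft_upper: bool = False

    def __post_init__(self) -> None:
        if self.dist not in ("log-uniform", "uniform"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if not self.lower < self.upper:
            raise ValueError("prior requires lower < upper")
        if self.dist == "log-uniform" and self.lower <= 0:
            raise ValueError("log-uniform prior requires lower > 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "log-uniform":
            return float(np.exp(rng.uniform(np.log(self.lower), np.log(self.upper))))
        return float(rng.uniform(self.lower, self.upper))


@dataclass(frozen=True)
class PriorSet:
    """Per-parameter priors plus the migration-rate unit convention.

    ``migration_unit`` is "migrants" when migration priors are expressed as
    forward migrant counts per generation (converted to backward per-lineage
    rates by dividing by the receiving deme's haploid size at evaluation
    time) or "rate" for backward per-lineage probabilities directly.
    """

    priors: dict
    migration_unit: str = "migrants"

    def __post_init__(self) -> None:
        if self.migration_unit not in ("migrants", "rate"):
            raise ValueError("migration_unit must be 'migrants' or 'rate'")

    def for_model(self, model: ModelSpec) -> dict:
        missing = [p for p in model.free_parameters if p not in self.priors]
        if missing:
            raise KeyError(f"prior missing for free parameters {missing}")
        return {p: self.priors[p] for p in model.free_parameters}


# Published sampling ranges for this system: haploid sizes log-uniform
# 5e4-1e6 (soft upper), divergence time uniform 0.5-1.0 My (soft upper),
# secondary contact uniform within the current interglacial (0-21 ky),
# migration log-uniform 0.001-20 migrants per generation.
def default_priors(migration_unit: str = "migrants") -> PriorSet:
    size = PriorSpec("log-uniform", 50_000.0, 1_000_000.0, soft_upper=True)
    priors = {name: size for name in ("N_eS", "N_eC", "N_eO", "N_eD", "N_eA")}
    priors["T_D"] = PriorSpec("uniform", 500_000.0, 1_000_000.0, soft_upper=True)
    priors["T_SC"] = PriorSpec("uniform", 0.0, 21_000.0)
    if migration_unit == "migrants":
        mig = PriorSpec("log-uniform", 0.001, 20.0, soft_upper=True)
    else:
        # same span re-expressed as a per-lineage probability at a typical
        # deme size of ~5e5 haploids
        mig = PriorSpec("log-uniform", 2e-9, 4e-5, soft_upper=True)
    for name in ("m", "m_S", "m_C"):
        priors[name] = mig
    return PriorSet(priors, migration_unit)


def draw_to_params(model: ModelSpec, draw: dict, migration_unit: str) -> ParameterVector:
    """Convert a prior-space draw to a canonical ParameterVector.

    Migrant-count draws M (forward) become backward per-lineage rates by
    dividing by the receiving deme's haploid size: forward S-to-C migrants
    enter the Chihuahuan deme, so a Chihuahuan lineage traces back to the
    Sonoran deme at rate M_S / N_eC (and symmetrically for M_C).
    """
    vals = dict(draw)
    if migration_unit == "migrants":
        if "m" in vals:
            # SYM: one shared count both ways; use the mean receiving size
            vals["m"] = min(vals["m"] * 2.0 / (vals["N_eC"] + vals["N_eS"]), 0.5)
        if "m_S" in vals:
            vals["m_S"] = min(vals["m_S"] / vals["N_eC"], 0.5)
        if "m_C" in vals:
            vals["m_C"] = min(vals["m_C"] / vals["N_eS"], 0.5)
    return ParameterVector.for_model(model, **vals)


def draw_parameters(model: ModelSpec, priors: PriorSet, seed: int) -> ParameterVector:
    """Draw one ParameterVector from the priors (reproducible under seed)."""
    rng = np.random.default_rng(seed)
    draw = draw_prior_space(model, priors, rng)
    return draw_to_params(model, draw, priors.migration_unit)


def draw_prior_space(model: ModelSpec, priors: PriorSet, rng: np.random.Generator) -> dict:
    """Draw the free parameters in prior units (before any rate conversion)."""
    spec = priors.for_model(model)
    draw = {name: spec[name].draw(rng) for name in model.free_parameters}
    # structural constraint: secondary contact cannot predate the divergence
    if "T_SC" in draw:
        draw["T_SC"] = min(draw["T_SC"], draw["T_D"])
    return draw


@dataclass(frozen=True)
class SampleConfig:
    """Haploid chromosome counts sampled per deme (Sonoran, Chihuahuan, outgroup)."""

    n_S: int
    n_C: int
    n_O: int

    def __post_init__(self) -> None:
        if min(self.n_S, self.n_C, self.n_O) < 0 or self.n_S + self.n_C + self.n_O < 2:
            raise ValueError("need at least two sampled chromosomes in total")

    @property
    def total(self) -> int:
        return self.n_S + self.n_C + self.n_O

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_S + 1, self.n_C + 1, self.n_O + 1)


def _kernel_args(model: ModelSpec, params: ParameterVector):
    """Translate a ParameterVector into generation-scaled kernel arguments."""
    params.validate()
    gen = GENERATION_TIME_YEARS
    t_div = params.T_D / gen
    t_anc = T_ANCESTRAL_YEARS / gen
    if model.model_id == "ISO":
        m_s2c = m_c2s = 0.0
        mig_end = 0.0
    elif model.model_id == "SECCONTACT":
        m_s2c, m_c2s = params.m_C, params.m_S
        mig_end = params.T_SC / gen
    else:
        m_s2c, m_c2s = params.m_C, params.m_S
        if model.model_id == "SON2CHI":
            m_s2c = 0.0
        elif model.model_id == "CHI2SON":
            m_c2s = 0.0
        mig_end = t_div
    sizes = np.array(
        [params.N_eS, params.N_eC, params.N_eO, params.N_eD, params.N_eA], dtype=np.float64
    )
    return sizes, t_div, t_anc, mig_end, m_s2c, m_c2s


@njit(cache=True)
def _simulate_batch(
    n1,
    n2,
    n3,
    sizes,
    t_div,
    t_anc,
    mig_end,
    m_s2c,
    m_c2s,
    reps,
    seed,
    sfs_acc,
    tmrca,
    totlen,
    cell_idx,
    members_out,
    collect_members,
):  # pragma: no cover - exercised via python wrappers
    n_tot = n1 + n2 + n3
    s2 = n2 + 1
    s3 = n3 + 1
    deme = np.empty(n_tot, dtype=np.int64)
    cnt = np.empty((n_tot, 3), dtype=np.int64)
    members = np.zeros((n_tot, n_tot), dtype=np.uint8)
    for rep in range(reps):
        np.random.seed((seed + 2654435761 * (rep + 1)) & 0x7FFFFFFF)
        for i in range(n_tot):
            if i < n1:
                deme[i] = 0
            elif i < n1 + n2:
                deme[i] = 1
            else:
                deme[i] = 2
            cnt[i, 0] = 0
            cnt[i, 1] = 0
            cnt[i, 2] = 0
            cnt[i, deme[i]] = 1
            if collect_members:
                for s in range(n_tot):
                    members[i, s] = 0
                members[i, i] = 1
        alive = n_tot
        t = 0.0
        length = 0.0
        w_res = 0.0
        merged = False
        while alive > 1:
            k0 = 0
            k1 = 0
            k2 = 0
            k3 = 0
            k4 = 0
            for i in range(alive):
                d = deme[i]
                if d == 0:
                    k0 += 1
                elif d == 1:
                    k1 += 1
                elif d == 2:
                    k2 += 1
                elif d == 3:
                    k3 += 1
                else:
                    k4 += 1
            r_c0 = 0.5 * k0 * (k0 - 1) / sizes[0]
            r_c1 = 0.5 * k1 * (k1 - 1) / sizes[1]
            r_c2 = 0.5 * k2 * (k2 - 1) / sizes[2]
            r_c3 = 0.5 * k3 * (k3 - 1) / sizes[3]
            r_c4 = 0.5 * k4 * (k4 - 1) / sizes[4]
            if t < mig_end:
                r_m0 = k0 * m_s2c
                r_m1 = k1 * m_c2s
            else:
                r_m0 = 0.0
                r_m1 = 0.0
            total = r_c0 + r_c1 + r_c2 + r_c3 + r_c4 + r_m0 + r_m1
            # next rate-change boundary
            if t < mig_end:
                nb = mig_end
            elif t < t_div:
                nb = t_div
            elif t < t_anc:
                nb = t_anc
            else:
                nb = 1.0e300
            if total > 0.0:
                dt = -math.log(np.random.random()) / total
            else:
                dt = 1.0e300
            t_event = t + dt
            if t_event < nb:
                seg_end = t_event
                hit_boundary = False
            else:
                seg_end = nb
                hit_boundary = True
            seg = seg_end - t
            # Rao-Blackwellized sojourn for the expected-SFS accumulator:
            # E[min(dt, nb - t) | state] instead of the realized draw, which
            # removes the exponential holding-time variance from the
            # branch-length estimate (the realized seg still drives the
            # reservoir and total length, which must describe one genealogy)
            if nb >= 1.0e299:
                seg_exp = 1.0 / total if total > 0.0 else 0.0
            elif total > 0.0:
                seg_exp = (1.0 - math.exp(-total * (nb - t))) / total
            else:
                seg_exp = nb - t
            if seg > 0.0 or seg_exp > 0.0:
                for i in range(alive):
                    sfs_acc[cnt[i, 0], cnt[i, 1], cnt[i, 2]] += seg_exp
                    length += seg
                    w_res += seg
                    if seg > 0.0 and np.random.random() * w_res < seg:
                        cell_idx[rep] = (cnt[i, 0] * s2 + cnt[i, 1]) * s3 + cnt[i, 2]
                        if collect_members:
                            for s in range(n_tot):
                                members_out[rep, s] = members[i, s]
            t = seg_end
            if hit_boundary:
                if nb == t_div:
                    for i in range(alive):
                        if deme[i] == 0 or deme[i] == 1:
                            deme[i] = 3
                elif nb == t_anc:
                    for i in range(alive):
                        deme[i] = 4
                # mig_end boundary: rates change, nothing to relabel
                continue
            # pick the event
            u = np.random.random() * total
            if u < r_c0:
                d_ev = 0
                is_coal = True
            elif u < r_c0 + r_c1:
                d_ev = 1
                is_coal = True
            elif u < r_c0 + r_c1 + r_c2:
                d_ev = 2
                is_coal = True
            elif u < r_c0 + r_c1 + r_c2 + r_c3:
                d_ev = 3
                is_coal = True
            elif u < r_c0 + r_c1 + r_c2 + r_c3 + r_c4:
                d_ev = 4
                is_coal = True
            elif u < r_c0 + r_c1 + r_c2 + r_c3 + r_c4 + r_m0:
                d_ev = 0
                is_coal = False
            else:
                d_ev = 1
                is_coal = False
            if is_coal:
                if d_ev == 0:
                    kd = k0
                elif d_ev == 1:
                    kd = k1
                elif d_ev == 2:
                    kd = k2
                elif d_ev == 3:
                    kd = k3
                else:
                    kd = k4
                a = int(np.random.random() * kd)
                b = int(np.random.random() * (kd - 1))
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                seen = 0
                for i in range(alive):
                    if deme[i] == d_ev:
                        if seen == a:
                            ia = i
                        if seen == b:
                            ib = i
                        seen += 1
                cnt[ia, 0] += cnt[ib, 0]
                cnt[ia, 1] += cnt[ib, 1]
                cnt[ia, 2] += cnt[ib, 2]
                if collect_members:
                    for s in range(n_tot):
                        if members[ib, s]:
                            members[ia, s] = 1
                last = alive - 1
                if ib != last:
                    deme[ib] = deme[last]
                    cnt[ib, 0] = cnt[last, 0]
                    cnt[ib, 1] = cnt[last, 1]
                    cnt[ib, 2] = cnt[last, 2]
                    if collect_members:
                        for s in range(n_tot):
                            members[ib, s] = members[last, s]
                alive -= 1
                merged = True
            else:
                kd = k0 if d_ev == 0 else k1
                a = int(np.random.random() * kd)
                seen = 0
                for i in range(alive):
                    if deme[i] == d_ev:
                        if seen == a:
                            deme[i] = 1 - d_ev
                            break
                        seen += 1
        tmrca[rep] = t
        totlen[rep] = length
    return merged


def _run_batch(
    model: ModelSpec,
    params: ParameterVector,
    config: SampleConfig,
    reps: int,
    seed: int,
    collect_members: bool = False,
):
    sizes, t_div, t_anc, mig_end, m_s2c, m_c2s = _kernel_args(model, params)
    sfs_acc = np.zeros(config.shape, dtype=np.float64)
    tmrca = np.empty(reps, dtype=np.float64)
    totlen = np.empty(reps, dtype=np.float64)
    cell_idx = np.empty(reps, dtype=np.int64)
    if collect_members:
        members = np.zeros((reps, config.total), dtype=np.uint8)
    else:
        members = np.zeros((1, 1), dtype=np.uint8)
    _simulate_batch(
        config.n_S,
        config.n_C,
        config.n_O,
        sizes,
        t_div,
        t_anc,
        mig_end,
        m_s2c,
        m_c2s,
        reps,
        int(seed) & 0x7FFFFFFF,
        sfs_acc,
        tmrca,
        totlen,
        cell_idx,
        members,
        collect_members,
    )
    return sfs_acc, tmrca, totlen, cell_idx, members


def simulate_tmrca(
    model: ModelSpec, params: ParameterVector, config: SampleConfig, reps: int, seed: int
) -> np.ndarray:
    """Times to the most recent common ancestor (generations), one per replicate."""
    _, tmrca, _, _, _ = _run_batch(model, params, config, reps, seed)
    return tmrca


def expected_sfs(
    model: ModelSpec,
    params: ParameterVector,
    config: SampleConfig,
    n_reps: int,
    seed: int,
    mu: float | None = None,
) -> JointSFS:
    """Monte-Carlo expected joint SFS (per-site mutation input units).

    Entry (i,j,k) is mu_per_generation times the mean total branch length
    subtending exactly (i,j,k) sampled chromosomes.  Monomorphic corners are
    masked.  Linear in mu by construction.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mu is None:
        mu = model.fixed["mu"] * model.fixed["generation_time"]
    sfs_acc, _, _, _, _ = _run_batch(model, params, config, n_reps, seed)
    counts = sfs_acc * (mu / n_reps)
    out = JointSFS(counts, (config.n_S, config.n_C, config.n_O), np.zeros_like(counts, bool))
    out.mask_corners()
    out.counts[out.mask] = 0.0
    return out


def _length_weighted_accept(
    totlen: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Accept replicates with probability proportional to total tree length.

    A random segregating site falls on a genealogy with probability
    proportional to its total branch length, so SNP-bearing genealogies are
    a length-biased sample of plain replicates.
    """
    lmax = float(totlen.max())
    return rng.random(totlen.size) * lmax < totlen


def sample_sfs(
    model: ModelSpec,
    params: ParameterVector,
    config: SampleConfig,
    n_snps: int,
    seed: int,
) -> JointSFS:
    """Sample an observed joint SFS of exactly ``n_snps`` segregating sites.

    One site per accepted genealogy; the mutated branch is chosen
    proportional to branch length, and genealogies are length-weighted so
    that cell probabilities match the normalized expected SFS.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    shape = config.shape
    counts = np.zeros(shape, dtype=float)
    collected = 0
    batch = max(2 * n_snps, 2000)
    sub = 0
    while collected < n_snps:
        _, _, totlen, cell_idx, _ = _run_batch(
            model, params, config, batch, seed + 7919 * sub + 1
        )
        accept = _length_weighted_accept(totlen, rng)
        cells = cell_idx[accept][: n_snps - collected]
        np.add.at(counts.reshape(-1), cells, 1.0)
        collected += cells.size
        sub += 1
        if sub > 50:
            raise RuntimeError("length-weighted sampling failed to converge")
    out = JointSFS(counts, (config.n_S, config.n_C, config.n_O), np.zeros(shape, bool))
    out.mask_corners()
    return out


_BASES = ("A", "C", "G", "T")


def sample_snp_matrix(
    model: ModelSpec,
    params: ParameterVector,
    n_individuals: tuple[int, int, int],
    n_snps: int,
    missing_rate: float,
    seed: int,
    ref_is_ancestral_prob: float = 0.5,
    pop_labels: tuple[str, str, str] = ("SON", "CHI", "CAR"),
) -> GenotypeMatrix:
    """Simulate a diploid SNP matrix (one segregating site per genealogy).

    ``n_individuals`` are diploid counts per deme; each individual is the
    pairing of two consecutive haploid lineages (genealogies are
    exchangeable within demes, so fixed pairing is equivalent in
    distribution to random pairing).  Each site's REF allele is the
    ancestral base with probability ``ref_is_ancestral_prob``, so
    downstream polarization is actually exercised.  MISSING cells are
    i.i.d. at ``missing_rate``.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    dS, dC, dO = n_individuals
    config = SampleConfig(2 * dS, 2 * dC, 2 * dO)
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    flips: list[bool] = []
    batch = max(2 * n_snps, 1000)
    sub = 0
    while len(rows) < n_snps:
        _, _, totlen, _, members = _run_batch(
            model, params, config, batch, seed + 104729 * sub + 3, collect_members=True
        )
        accept = np.nonzero(_length_weighted_accept(totlen, rng))[0]
        for idx in accept[: n_snps - len(rows)]:
            derived = members[idx]
            dosage = derived[0::2].astype(np.int8) + derived[1::2].astype(np.int8)
            flip = bool(rng.random() >= ref_is_ancestral_prob)
            rows.append(2 - dosage if flip else dosage)
            flips.append(flip)
        sub += 1
        if sub > 50:
            raise RuntimeError("length-weighted sampling failed to converge")
    calls = np.array(rows, dtype=np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    sites = []
    for s in range(n_snps):
        anc, other = rng.choice(4, size=2, replace=False)
        ref, alt = (_BASES[other], _BASES[anc]) if flips[s] else (_BASES[anc], _BASES[other])
        sites.append(SiteRecord(f"locus_{s:06d}", 1 + int(rng.integers(100)), f"L{s:06d}", ref, alt))
    individuals, pop_of = [], {}
    for label, count in zip(pop_labels, (dS, dC, dO)):
        for i in range(count):
            name = f"{label}_{i:03d}"
            individuals.append(name)
            pop_of[name] = label
    return GenotypeMatrix(
        sites,
        calls,
        individuals,
        pop_of,
        meta={"seed": seed, "flipped_sites": np.nonzero(flips)[0]},
    )


@dataclass(frozen=True)
class BranchRecord:
    """A genealogy branch: subtended sample counts per deme and its length (generations)."""

    counts: tuple[int, int, int]
    length: float


def simulate_genealogy(
    model: ModelSpec, params: ParameterVector, config: SampleConfig, seed: int
) -> tuple[list[BranchRecord], float]:
    """Pure-Python structured-coalescent reference for a single genealogy.

    Returns the per-branch records (one per coalesced lineage; the root
    branch has no record) and the TMRCA in generations.  Kept independent
    of the numba kernel so the two can be cross-checked.
    """
    sizes, t_div, t_anc, mig_end, m_s2c, m_c2s = _kernel_args(model, params)
    rng = np.random.default_rng(seed)
    lineages = []  # [deme, counts(3), birth_time]
    for d, n in ((0, config.n_S), (1, config.n_C), (2, config.n_O)):
        for _ in range(n):
            c = [0, 0, 0]
            c[d] = 1
            lineages.append([d, c, 0.0])
    records: list[BranchRecord] = []
    t = 0.0
    while len(lineages) > 1:
        k = [0] * 5
        for lin in lineages:
            k[lin[0]] += 1
        coal = [0.5 * k[d] * (k[d] - 1) / sizes[d] for d in range(5)]
        mig = [k[0] * m_s2c, k[1] * m_c2s] if t < mig_end else [0.0, 0.0]
        total = sum(coal) + sum(mig)
        if t < mig_end:
            nb = mig_end
        elif t < t_div:
            nb = t_div
        elif t < t_anc:
            nb = t_anc
        else:
            nb = math.inf
        dt = rng.exponential(1.0 / total) if total > 0 else math.inf
        if t + dt >= nb:
            t = nb
            if nb == t_div:
                for lin in lineages:
                    if lin[0] in (0, 1):
                        lin[0] = 3
            elif nb == t_anc:
                for lin in lineages:
                    lin[0] = 4
            continue
        t += dt
        u = rng.random() * total
        acc = 0.0
        event = None
        for d in range(5):
            acc += coal[d]
            if u < acc:
                event = ("coal", d)
                break
        if event is None:
            event = ("mig", 0) if u < acc + mig[0] else ("mig", 1)
        if event[0] == "coal":
            d = event[1]
            here = [i for i, lin in enumerate(lineages) if lin[0] == d]
            ia, ib = rng.choice(len(here), size=2, replace=False)
            ia, ib = here[ia], here[ib]
            for lin_idx in (ia, ib):
                lin = lineages[lin_idx]
                records.append(BranchRecord(tuple(lin[1]), t - lin[2]))
            merged = [
                d,
                [a + b for a, b in zip(lineages[ia][1], lineages[ib][1])],
                t,
            ]
            lineages = [lin for i, lin in enumerate(lineages) if i not in (ia, ib)]
            lineages.append(merged)
        else:
            d = event[1]
            here = [i for i, lin in enumerate(lineages) if lin[0] == d]
            lineages[here[int(rng.integers(len(here)))]][0] = 1 - d
    return records, t


def expected_sfs_reference(
    model: ModelSpec,
    params: ParameterVector,
    config: SampleConfig,
    n_reps: int,
    seed: int,
    mu: float | None = None,
) -> JointSFS:
    """Expected SFS accumulated from the pure-Python reference simulator."""
    if mu is None:
        mu = model.fixed["mu"] * model.fixed["generation_time"]
    counts = np.zeros(config.shape)
    for rep in range(n_reps):
        records, _ = simulate_genealogy(model, params, config, seed + rep)
        for rec in records:
            counts[rec.counts] += rec.length
    counts *= mu / n_reps
    out = JointSFS(counts, (config.n_S, config.n_C, config.n_O), np.zeros_like(counts, bool))
    out.mask_corners()
    out.counts[out.mask] = 0.0
    return out
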
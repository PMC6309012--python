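"""Synthetic genotype and playback datasets with the structure the analyses assume.

The genotype generator wraps the structured-coalescent SNP sampler and
writes VCF + population-map files that round-trip through the SFS builder;
its default parameters are the best-supported asymmetric-migration
estimates for Sonoran and Chihuahuan Northern Cardinals with the *carneus*
outgroup, so tests operate at a realistic point of parameter space.  The
playback generator draws per-trial latent aggression from the same additive
structure the mixed models assume (treatment effect + pre-treatment slope +
site and stimulus-set intercepts + residual) and emits the five raw
measures, including a binned distance series, per experimental period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalescent as co
from .behavior import DISTANCE_BINS, TREATMENTS
from .sfs import MISSING, GenotypeMatrix

#: Best-supported (asymmetric-migration) parameter estimates for the
#: cardinal system: haploid effective sizes, divergence time in years, and
#: migration expressed as forward migrants per generation (the estimated
#: rates are minute: about one migrant per hundred thousand generations).
REFERENCE_ASYM_MIGRANTS = {
    "N_eS": 153_451.0,
    "N_eC": 706_389.0,
    "N_eO": 212_169.0,
    "N_eD": 776_869.0,
    "N_eA": 181_138.0,
    "T_D": 991_414.0,
    "m_S": 1.18e-5,
    "m_C": 1.02e-5,
}


def reference_asym_params() -> co.ParameterVector:
    """The reference parameter point as a canonical ParameterVector."""
    return co.draw_to_params(
        co.get_model("ASYM"), dict(REFERENCE_ASYM_MIGRANTS), "migrants"
    )


@dataclass
class GenotypeScenario:
    """A synthetic SNP-matrix scenario (diploid individual counts per population)."""

    model_id: str = "ASYM"
    params: co.ParameterVector = field(default_factory=reference_asym_params)
    n_individuals: tuple[int, int, int] = (54, 31, 3)  # SON, CHI, CAR diploids
    n_outgroup_individuals: int = 2
    n_snps: int = 20_000
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def make_genotype_matrix(scenario: GenotypeScenario) -> GenotypeMatrix:
    """Simulate the diploid SNP matrix plus perfect-outgroup individuals.

    The appended OUTGROUP individuals carry the ancestral allele
    homozygously at every site; they exist to let the polarization step run
    on synthetic data and are not part of the demographic model's samples.
    """
    model = co.get_model(scenario.model_id)
    gm = co.sample_snp_matrix(
        model,
        scenario.params,
        scenario.n_individuals,
        scenario.n_snps,
        scenario.missing_rate,
        scenario.seed,
    )
    n_out = scenario.n_outgroup_individuals
    if n_out:
        # outgroup individuals are homozygous for the ancestral allele: REF
        # dosage 0 normally, ALT dosage 2 where the generator swapped REF/ALT
        anc_calls = np.zeros((gm.n_sites, n_out), dtype=np.int8)
        flips = gm.meta.get("flipped_sites")
        if flips is None:
            raise RuntimeError("generator did not record site orientation")
        anc_calls[flips, :] = 2
        individuals = list(gm.individuals)
        pop_of = dict(gm.pop_of)
        for i in range(n_out):
            name = f"OUT_{i:03d}"
            individuals.append(name)
            pop_of[name] = "OUTGROUP"
        gm = GenotypeMatrix(
            gm.sites,
            np.hstack([gm.calls, anc_calls]),
            individuals,
            pop_of,
            meta=dict(gm.meta),
        )
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT-only) for a GenotypeMatrix."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in gm.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for s, site in enumerate(gm.sites):
            calls = "\t".join(gt[int(c)] for c in gm.calls[s])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.locus_id}\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_popmap(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for ind in gm.individuals:
            fh.write(f"{ind}\t{gm.pop_of[ind]}\n")


def make_genotype_dataset(
    scenario: GenotypeScenario, outdir
) -> tuple[GenotypeMatrix, Path, Path]:
    """Simulate a genotype matrix and write VCF + popmap (+ metadata) files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm = make_genotype_matrix(scenario)
    vcf_path = outdir / "genotypes.vcf"
    popmap_path = outdir / "popmap.tsv"
    write_vcf(gm, vcf_path)
    write_popmap(gm, popmap_path)
    meta = outdir / "scenario.txt"
    with open(meta, "w") as fh:
        fh.write(f"model_id\t{scenario.model_id}\n")
        fh.write(f"n_individuals\t{scenario.n_individuals}\n")
        fh.write(f"n_snps\t{scenario.n_snps}\n")
        fh.write(f"missing_rate\t{scenario.missing_rate}\n")
        fh.write(f"seed\t{scenario.seed}\n")
        for name in ("N_eS", "N_eC", "N_eO", "N_eD", "N_eA", "T_D", "T_SC", "m_S", "m_C"):
            fh.write(f"{name}\t{getattr(scenario.params, name)!r}\n")
    return gm, vcf_path, popmap_path


@dataclass
class PlaybackScenario:
    """A synthetic playback experiment.

    Latent per-trial aggression is ``treatment effect + pre_effect *
    pre-latent + site intercept + stimulus-set intercept + residual``; the
    five measures are noisy monotone transforms of the latent (counts
    rounded at zero, call presence thresholded, distance series binned).
    ``measure_noise_sd`` sets how much independent noise each measure adds
    and is calibrated so the first principal component explains roughly 55%
    of the Response-period variance at defaults, matching what field
    playback data typically yield.
    """

    n_sites: tuple[int, int] = (67, 61)  # Sonoran, Chihuahuan
    treatment_effects: dict = field(
        default_factory=lambda: {"LOCAL": 1.5, "DISTANT": 0.0, "ACROSS": 0.0, "CONTROL": 0.0}
    )
    pre_effect: float = 0.4
    pre_latent_sd: float = 1.0  # spread of baseline (pre-playback) aggression across sites
    site_sd: float = 0.2
    stimulus_sd: float = 0.3
    residual_sd: float = 0.6
    n_stimulus_sets: int = 6
    detection_rate: float = 1.0
    n_undetected: tuple[int, int] | None = None
    measure_loadings: tuple[float, ...] = (1.0, 1.0, 1.0, -1.0, -1.0)
    measure_noise_sd: float = 1.4
    distance_jitter_sd: float = 4.0  # within-series jitter around the latent distance
    far_code: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.detection_rate <= 1:
            raise ValueError("detection_rate must be in (0, 1]")
        if min(self.site_sd, self.stimulus_sd, self.residual_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if set(self.treatment_effects) != set(TREATMENTS):
            raise ValueError(f"treatment_effects must cover {TREATMENTS}")


_BIN_EDGES = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 24.0])


def _distance_series(
    latent: float, rng: np.random.Generator, jitter_sd: float, n_obs: int = 18
) -> str:
    """Map latent proximity to a series of field distance bins.

    The underlying distance is a linear transform of the latent with
    Gaussian jitter, clamped to the observable range, then binned by the
    field thresholds; coefficients chosen so the marginal bin distribution
    is non-degenerate at default scenario parameters.
    """
    d = 12.0 + 5.0 * latent + rng.normal(0.0, jitter_sd, size=n_obs)
    d = np.clip(d, 0.1, 40.0)
    idx = np.searchsorted(_BIN_EDGES, d)
    return ";".join(DISTANCE_BINS[i] for i in idx)


def make_playback_dataset(scenario: PlaybackScenario) -> pd.DataFrame:
    """Generate the trial table: one row per site x treatment x period.

    Undetected sites keep their rows but with missing measures, mirroring
    field sheets where the site was visited and no male appeared.
    """
    rng = np.random.default_rng(scenario.seed)
    deserts = ("SON", "CHI")
    rows = []
    for d_idx, desert in enumerate(deserts):
        n_sites = scenario.n_sites[d_idx]
        site_ids = [f"{desert}_S{i:03d}" for i in range(n_sites)]
        if scenario.n_undetected is not None:
            undetected = set(
                rng.choice(n_sites, size=scenario.n_undetected[d_idx], replace=False)
            )
        else:
            undetected = {
                i for i in range(n_sites) if rng.random() > scenario.detection_rate
            }
        stim_effects = {
            (t, j): rng.normal(0.0, scenario.stimulus_sd)
            for t in TREATMENTS
            for j in range(scenario.n_stimulus_sets)
        }
        for i, site in enumerate(site_ids):
            site_eff = rng.normal(0.0, scenario.site_sd)
            pre_latent = rng.normal(0.0, scenario.pre_latent_sd)
            detected = i not in undetected
            for treatment in TREATMENTS:
                j = int(rng.integers(scenario.n_stimulus_sets))
                stim_id = f"{desert}_{treatment}_{j}"
                a = (
                    scenario.treatment_effects[treatment]
                    + scenario.pre_effect * pre_latent
                    + site_eff
                    + stim_effects[(treatment, j)]
                    + rng.normal(0.0, scenario.residual_sd)
                )
                for period, latent in (("PRE", pre_latent), ("PLAYBACK", a), ("POST", a)):
                    if not detected:
                        rows.append(
                            {
                                "site_id": site,
                                "desert": desert,
                                "treatment": treatment,
                                "stimulus_set_id": stim_id,
                                "period": period,
                                "flybys": np.nan,
                                "calls_present": np.nan,
                                "close_songs": np.nan,
                                "far_songs": np.nan,
                                "distance_series": np.nan,
                                "closest_distance": np.nan,
                            }
                        )
                        continue
                    lam = scenario.measure_loadings
                    noise = rng.normal(0.0, scenario.measure_noise_sd, size=5)
                    m = [lam[q] * latent + noise[q] for q in range(5)]
                    series = _distance_series(m[4], rng, scenario.distance_jitter_sd)
                    from .behavior import bin_to_meters

                    closest = min(
                        bin_to_meters(b, scenario.far_code) for b in series.split(";")
                    )
                    rows.append(
                        {
                            "site_id": site,
                            "desert": desert,
                            "treatment": treatment,
                            "stimulus_set_id": stim_id,
                            "period": period,
                            "flybys": float(max(0, round(3.0 + 2.0 * m[0]))),
                            "calls_present": float(m[1] > 0.0),
                            "close_songs": float(max(0, round(4.0 + 2.0 * m[2]))),
                            "far_songs": float(max(0, round(4.0 + 2.0 * m[3]))),
                            "distance_series": series,
                            "closest_distance": closest,
                        }
                    )
    return pd.DataFrame(rows)


def trial_counts(trials: pd.DataFrame) -> tuple[int, int]:
    """(total trials, trials at detected sites); a trial is one site x treatment."""
    keys = ["site_id", "treatment"]
    total = len(trials[keys].drop_duplicates())
    detected = len(trials.dropna(subset=["flybys"])[keys].drop_duplicates())
    return total, detected
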
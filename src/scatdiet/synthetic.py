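"""Ground-truthed synthetic scat-metabarcoding datasets.

Emulates the design of a multi-season carnivore diet survey: scats collected
over a handful of sites across four seasonal sampling windows, each extract
amplified in three PCR replicates on a short (~100 bp) vertebrate marker.
Host DNA is only partly suppressed (blocking oligonucleotides), diet-taxon
presence follows a logistic occurrence model driven by season and by field
vole availability, reads are allocated compositionally with overdispersion,
and the usual sequencing artifacts are injected on top: error-variant
sequences, one-read noise sequences, tag jumps and human contamination.

Every draw comes from a single :class:`numpy.random.Generator`, so a config
plus seed reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .tables import MOTUTable, ReferenceDB, build_pcr_index

SEASON_LABELS = ("winter2018", "spring2018", "winter2019", "spring2019")

HOST = "host"
DIET = "diet"
CONTAMINANT = "contaminant"


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class OccurrenceModel:
    """Logistic ground-truth model for per-sample diet presence.

    Vole availability in a site x season cell is the inverse-logit of the
    season intercept plus site-level noise; a sample's vole presence is a
    Bernoulli draw at that availability.  Dog presence is Bernoulli at
    ``invlogit(dog_intercept + dog_vole_slope * availability)`` — a negative
    slope makes dog an alternative resource used when voles are scarce.
    Remaining diet taxa occur independently at a flat probability.
    """

    season_intercepts: tuple[float, ...] = (2.6, 0.75, -1.45, -0.55)
    dog_intercept: float = 0.3
    dog_vole_slope: float = -2.5
    other_diet_prob: float = 0.3
    site_sd: float = 0.5

    def validate(self) -> None:
        vals = (*self.season_intercepts, self.dog_intercept,
                self.dog_vole_slope, self.other_diet_prob, self.site_sd)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("occurrence-model coefficients must be finite")
        if not 0.0 <= self.other_diet_prob <= 1.0:
            raise ValueError("other_diet_prob must be in [0, 1]")


DEFAULT_TAXA: tuple[tuple[str, str], ...] = (
    ("Vulpes vulpes", HOST),
    ("Martes martes", HOST),
    ("Microtus agrestis", DIET),
    ("Canis lupus familiaris", DIET),
    ("Myodes glareolus", DIET),
    ("Oryctolagus cuniculus", DIET),
    ("Homo sapiens", CONTAMINANT),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic survey; defaults mirror the emulated study.

    Five sites x four seasons with ~34 scats per cell gives a dataset of the
    study's order of magnitude (hundreds of host-assigned samples per
    predator); three PCR replicates per scat; host amplification 70%
    suppressed by default.  Artifact rates default to low values typical of
    a curated metabarcoding run.
    """

    n_sites: int = 5
    n_seasons: int = 4
    samples_per_site_season: int = 34
    taxon_list: tuple[tuple[str, str], ...] = DEFAULT_TAXA
    host_blocking_efficiency: float = 0.7
    reads_mean: float = 5000.0
    reads_dispersion: float = 2.0
    occurrence_model: OccurrenceModel = field(default_factory=OccurrenceModel)
    dirichlet_concentration: float = 1.0
    host_dirichlet_weight: float = 10.0
    tag_jump_rate: float = 0.002
    contamination_rate: float = 0.02
    error_motu_rate: float = 0.002
    singleton_rate: float = 2.0
    field_mislabel_rate: float = 0.2
    vole_taxon: str = "Microtus agrestis"
    dog_taxon: str = "Canis lupus familiaris"
    seq_length: int = 100
    min_pairwise_distance: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name, value in (
            ("host_blocking_efficiency", self.host_blocking_efficiency),
            ("contamination_rate", self.contamination_rate),
            ("error_motu_rate", self.error_motu_rate),
            ("field_mislabel_rate", self.field_mislabel_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.tag_jump_rate < 1.0:
            raise ValueError("tag_jump_rate must be in [0, 1)")
        if self.n_seasons < 1:
            raise ValueError("n_seasons must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.reads_mean <= 0:
            raise ValueError("reads_mean must be positive")
        if self.reads_dispersion <= 0:
            raise ValueError("reads_dispersion must be positive")
        if self.dirichlet_concentration <= 0 or self.host_dirichlet_weight <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.singleton_rate < 0:
            raise ValueError("singleton_rate must be >= 0")
        if len(self.occurrence_model.season_intercepts) < self.n_seasons:
            raise ValueError("need one season intercept per season")
        self.occurrence_model.validate()

    @property
    def season_labels(self) -> list[str]:
        labels = list(SEASON_LABELS[: self.n_seasons])
        labels += [f"season{k + 1}" for k in range(len(labels), self.n_seasons)]
        return labels

    def taxa_with_role(self, role: str) -> list[str]:
        return [name for name, r in self.taxon_list if r == role]


@dataclass
class SyntheticTruth:
    """Generator ground truth, snapshotted before artifact injection."""

    hosts: dict[str, str]                 # sample_id -> true host taxon
    diets: dict[str, frozenset[str]]      # sample_id -> taxa actually ingested
    pre_artifact_counts: pd.DataFrame     # taxon x PCR read counts, artifact-free
    vole_availability: pd.DataFrame       # columns site_id, season, availability
    config: GeneratorConfig

    def __post_init__(self) -> None:
        for sample, diet in self.diets.items():
            if self.hosts[sample] in diet:
                raise ValueError(f"true diet of {sample} contains its own host")


# -- reference database ----------------------------------------------------

def generate_reference_db(config: GeneratorConfig) -> ReferenceDB:
    """Random ~100 bp reference sequences, well separated between taxa.

    Sequences are drawn uniformly over {A,C,G,T} and accepted only if their
    edit distance to every previously accepted taxon is at least
    ``min_pairwise_distance`` (mirroring the clear inter-species separation
    a short vertebrate marker shows between, e.g., fox and dog).
    """
    config.validate()
    names = [name for name, _ in config.taxon_list]
    if len(names) < 2:
        raise ValueError("need at least 2 taxa for a reference database")
    if config.min_pairwise_distance > config.seq_length:
        raise ValueError("min_pairwise_distance cannot exceed sequence length")
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    for name in names:
        for _ in range(10_000):
            seq = "".join(rng.choice(alphabet, size=config.seq_length))
            if all(
                edlib.align(seq, other, mode="NW")["editDistance"]
                >= config.min_pairwise_distance
                for other in sequences.values()
            ):
                sequences[name] = seq
                break
        else:
            raise ValueError(
                "could not satisfy the divergence constraint at the requested length"
            )
    ranks = {name: ("species" if " " in name else "genus") for name in names}
    return ReferenceDB(sequences=sequences, ranks=ranks)


# -- dataset ---------------------------------------------------------------

def _negative_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _mutate(rng: np.random.Generator, seq: str) -> str:
    """Single random substitution — an amplification/sequencing error variant."""
    pos = int(rng.integers(len(seq)))
    alternatives = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + alternatives[int(rng.integers(3))] + seq[pos + 1:]


def generate_dataset(
    config: GeneratorConfig,
    reference_db: ReferenceDB | None = None,
) -> tuple[MOTUTable, pd.DataFrame, SyntheticTruth]:
    """Simulate a full survey: MOTU read table, metadata, and ground truth.

    Returns
    -------
    table
        Raw MOTU x PCR read table with artifacts injected.
    metadata
        One row per scat: sample_id, site_id, season, coordinates and the
        (possibly wrong) field species guess.
    truth
        Pre-artifact counts plus the true host and diet of every sample.
    """
    config.validate()
    if config.samples_per_site_season < 1:
        raise ValueError("samples_per_site_season must be >= 1")
    if reference_db is None:
        reference_db = generate_reference_db(config)
    rng = np.random.default_rng(config.seed + 1)

    hosts = config.taxa_with_role(HOST)
    diet_taxa = config.taxa_with_role(DIET)
    contaminants = config.taxa_with_role(CONTAMINANT)
    if not hosts or not diet_taxa:
        raise ValueError("taxon_list needs at least one host and one diet taxon")
    model = config.occurrence_model

    sites = [f"S{i + 1}" for i in range(config.n_sites)]
    site_xy = {s: (float(rng.uniform(0, 20)), float(rng.uniform(0, 20))) for s in sites}
    seasons = config.season_labels

    # per site x season vole availability in [0, 1]
    avail_rows = []
    availability: dict[tuple[str, str], float] = {}
    for si, season in enumerate(seasons):
        for site in sites:
            a = _invlogit(model.season_intercepts[si] + rng.normal(0.0, model.site_sd))
            availability[(site, season)] = a
            avail_rows.append({"site_id": site, "season": season, "availability": a})

    meta_rows = []
    truth_hosts: dict[str, str] = {}
    truth_diets: dict[str, frozenset[str]] = {}
    pcr_ids: list[str] = []
    # taxon-level pre-artifact counts, filled per PCR
    true_counts: dict[str, dict[str, int]] = {name: {} for name, _ in config.taxon_list}

    n = 0
    for season in seasons:
        si = seasons.index(season)
        for site in sites:
            a = availability[(site, season)]
            p_dog = _invlogit(model.dog_intercept + model.dog_vole_slope * a)
            for _ in range(config.samples_per_site_season):
                n += 1
                sample = f"SC{n:05d}"
                host = hosts[int(rng.integers(len(hosts)))]
                diet: set[str] = set()
                for taxon in diet_taxa:
                    if taxon == config.vole_taxon:
                        p = a
                    elif taxon == config.dog_taxon:
                        p = p_dog
                    else:
                        p = model.other_diet_prob
                    if rng.uniform() < p:
                        diet.add(taxon)
                diet.discard(host)
                truth_hosts[sample] = host
                truth_diets[sample] = frozenset(diet)

                guess = host
                if rng.uniform() < config.field_mislabel_rate and len(hosts) > 1:
                    others = [h for h in hosts if h != host]
                    guess = others[int(rng.integers(len(others)))]
                x0, y0 = site_xy[site]
                meta_rows.append({
                    "sample_id": sample, "site_id": site, "season": season,
                    "x_coord": round(x0 + float(rng.uniform(-1.5, 1.5)), 4),
                    "y_coord": round(y0 + float(rng.uniform(-1.5, 1.5)), 4),
                    "field_species_guess": guess,
                })

                present = [host] + sorted(diet)
                alpha = np.full(len(present), config.dirichlet_concentration)
                for rep in (1, 2, 3):
                    pcr = f"{sample}.R{rep}"
                    pcr_ids.append(pcr)
                    depth = _negative_binomial(rng, config.reads_mean, config.reads_dispersion)
                    shares = rng.dirichlet(alpha)
                    # host DNA dominates the extract before blocking
                    shares[0] *= config.host_dirichlet_weight
                    shares /= shares.sum()
                    shares[0] *= 1.0 - config.host_blocking_efficiency
                    total = shares.sum()
                    if total == 0 or depth == 0:
                        counts = np.zeros(len(present), dtype=int)
                    else:
                        counts = rng.multinomial(depth, shares / total)
                    for taxon, c in zip(present, counts):
                        if c:
                            true_counts[taxon][pcr] = int(c)
                # a scat always contains what was eaten: guarantee >= 1 read
                for taxon in diet:
                    if not any(true_counts[taxon].get(f"{sample}.R{r}") for r in (1, 2, 3)):
                        rep = int(rng.integers(1, 4))
                        key = f"{sample}.R{rep}"
                        true_counts[taxon][key] = true_counts[taxon].get(key, 0) + 1

    metadata = pd.DataFrame(meta_rows)
    taxa_order = [name for name, _ in config.taxon_list]
    pre_artifact = pd.DataFrame(0, index=taxa_order, columns=pcr_ids, dtype=int)
    for taxon, row in true_counts.items():
        for pcr, c in row.items():
            pre_artifact.at[taxon, pcr] = c

    # -- artifact injection -------------------------------------------------
    # working table keyed by sequence string
    seq_counts: dict[str, np.ndarray] = {}
    npcr = len(pcr_ids)
    for taxon in taxa_order:
        vec = pre_artifact.loc[taxon].to_numpy().copy()
        if vec.any():
            seq_counts[reference_db.sequences[taxon]] = vec

    # 1) error-variant sequences: each read independently may be a 1-mismatch copy
    if config.error_motu_rate > 0:
        for seq in list(seq_counts):
            vec = seq_counts[seq]
            errors = rng.binomial(vec, config.error_motu_rate)
            if errors.sum() == 0:
                continue
            vec -= errors
            for j in np.nonzero(errors)[0]:
                variant = _mutate(rng, seq)
                seq_counts.setdefault(variant, np.zeros(npcr, dtype=int))[j] += int(errors[j])

    # 2) one-read noise sequences (PCR/sequencing junk), variable lengths
    alphabet = np.array(list("ACGT"))
    if config.singleton_rate > 0:
        for j in range(npcr):
            for _ in range(int(rng.poisson(config.singleton_rate))):
                length = int(rng.integers(40, 141))
                junk = "".join(rng.choice(alphabet, size=length))
                seq_counts.setdefault(junk, np.zeros(npcr, dtype=int))[j] += 1

    # 3) tag jumps: a small fraction of each sequence's reads lands in the
    #    wrong PCR column; per-sequence totals are conserved
    if config.tag_jump_rate > 0 and npcr > 1:
        for seq, vec in seq_counts.items():
            total = int(vec.sum())
            n_jump = int(rng.binomial(total, config.tag_jump_rate))
            if n_jump == 0:
                continue
            sources = rng.multinomial(n_jump, vec / total)
            sources = np.minimum(sources, vec)
            vec -= sources
            for _ in range(int(sources.sum())):
                vec[int(rng.integers(npcr))] += 1

    # 4) contamination: occasional blocks of (mostly human) reads
    for taxon in contaminants:
        cseq = reference_db.sequences[taxon]
        for j in range(npcr):
            if rng.uniform() < config.contamination_rate:
                reads = 10 + int(rng.poisson(40))
                seq_counts.setdefault(cseq, np.zeros(npcr, dtype=int))[j] += reads

    order = sorted(seq_counts)
    motu_ids = [f"M{k + 1:05d}" for k in range(len(order))]
    table = MOTUTable(
        sequences=pd.Series(order, index=motu_ids, name="sequence"),
        counts=pd.DataFrame(
            np.vstack([seq_counts[s] for s in order]) if order else
            np.zeros((0, npcr), dtype=int),
            index=motu_ids, columns=pcr_ids,
        ),
        pcr_index=build_pcr_index(pcr_ids),
    )
    truth = SyntheticTruth(
        hosts=truth_hosts,
        diets=truth_diets,
        pre_artifact_counts=pre_artifact,
        vole_availability=pd.DataFrame(avail_rows),
        config=config,
    )
    return table, metadata, truth


# -- calorimetry -----------------------------------------------------------

def generate_calorimetry_table(
    n_dogs: int,
    mean_energy: float = 14.47,
    sd: float = 2.2,
    water_fraction: float = 0.605,
    mineral_fraction_dry: float = 0.307,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic bomb-calorimetry bench sheet for dog faeces.

    One row per combustion replicate: pellet wet/dry weights consistent with
    ``water_fraction``, gross energy (MJ per dry kg) whose replicate spread
    satisfies the <1.5% relative-standard-deviation acceptance rule by
    construction, and a non-combustible mineral residue.
    """
    if n_dogs < 1:
        raise ValueError("n_dogs must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not 0.0 < water_fraction < 1.0:
        raise ValueError("water_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(1, n_dogs + 1):
        dog_mean = mean_energy + float(rng.normal(0.0, sd)) if sd > 0 else mean_energy
        dog_mean = max(dog_mean, 1.0)
        n_rep = int(rng.integers(2, 5))
        # replicate noise bounded so that RSD stays safely below 1.5%
        rep_sd = 0.004 * dog_mean
        for r in range(1, n_rep + 1):
            dry = round(float(rng.uniform(0.15, 0.25)), 4)
            wet = dry / (1.0 - water_fraction)  # unrounded: keeps water fraction exact
            energy = dog_mean + float(rng.normal(0.0, rep_sd)) if sd > 0 else dog_mean
            rows.append({
                "dog_id": f"D{d}",
                "replicate": r,
                "wet_g": wet,
                "dry_g": dry,
                "gross_energy_MJ_per_dry_kg": round(energy, 4),
                "mineral_residue_g": round(dry * mineral_fraction_dry, 5),
            })
    return pd.DataFrame(rows)


def write_dataset(
    out_dir: str | Path,
    table: MOTUTable,
    metadata: pd.DataFrame,
    truth: SyntheticTruth,
    reference_db: ReferenceDB,
) -> dict[str, str]:
    """Write all generated artifacts under one directory; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference_db.to_fasta(out / "reference_db.fasta")
    table.to_tsv(out / "motu_table.tsv")
    metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth.pre_artifact_counts.to_csv(out / "truth_counts.tsv", sep="\t", index_label="taxon")
    truth_df = pd.DataFrame({
        "sample_id": list(truth.hosts),
        "true_host": [truth.hosts[s] for s in truth.hosts],
        "true_diet": [";".join(sorted(truth.diets[s])) for s in truth.hosts],
    })
    truth_df.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    truth.vole_availability.to_csv(out / "vole_availability.tsv", sep="\t", index=False)
    manifest = {
        "reference_db": "reference_db.fasta",
        "motu_table": "motu_table.tsv",
        "metadata": "metadata.tsv",
        "truth_counts": "truth_counts.tsv",
        "truth_samples": "truth_samples.tsv",
        "vole_availability": "vole_availability.tsv",
        "seed": str(truth.config.seed),
    }
    pd.Series(manifest).to_csv(out / "manifest.tsv", sep="\t", header=False)
    return manifest
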
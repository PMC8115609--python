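"""Synthetic multi-study mother-infant cohort generator with known ground truth.

The generator emulates the four inputs of the real meta-analysis — a
MetaPhlAn2-style species table, a HUMAnN2-style pathway table, per-species
aligned dominant-strain SNP haplotypes, and a sample-metadata table — under a
generative model with explicit vertical transmission:

* each species has a pool of population strains derived from one ancestral
  haplotype mutated at ``between_strain_divergence`` per site;
* a mother carries a species with probability ``prevalence_mother`` and hosts
  one dominant population strain;
* a carried species seeds the infant with probability ``transmission_prob``
  (multiplied by ``delivery_effect`` for C-section births); the transmitted
  strain is the mother's strain copied with per-site mutation probability
  ``within_strain_mut_rate``;
* otherwise the infant may acquire an unrelated population strain
  environmentally (``prevalence_infant_base``, scaled by ``feeding_effect``
  for non-exclusively breastfed infants), becoming detectable from a random
  acquisition day so the infant's species repertoire grows with age;
* every emitted haplotype is the host strain plus i.i.d. per-sample noise at
  ``within_strain_mut_rate``; mothers may switch dominant strains between
  timepoints (strain replacement), infants by default do not.

Relative abundances are log-normal and renormalized to sum to 100 per sample;
pathway abundances are carrier-species abundances times per-species pathway
weights, emitted both at community level and with ``|g__X.s__Y`` stratified
rows.  Identical (config, seed) yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .profiles_io import (AbundanceTable, write_humann_pathways,
                          write_metadata, write_metaphlan_table)
from .strain_analysis import HaplotypeAlignment, write_haplotype_fasta

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised when a cohort configuration is invalid."""


@dataclass(frozen=True)
class SpeciesSpec:
    """Generative parameters of one species.

    ``name`` is a full MetaPhlAn-style taxonomy string ending in ``s__...``.
    """

    name: str
    prevalence_mother: float = 0.7
    prevalence_infant_base: float = 0.3
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.0
    transmission_prob: float = 0.6
    within_strain_mut_rate: float = 0.001
    between_strain_divergence: float = 0.05
    delivery_effect: float = 1.0
    feeding_effect: float = 1.0

    def validate(self) -> None:
        for attr in ("prevalence_mother", "prevalence_infant_base",
                     "transmission_prob", "within_strain_mut_rate",
                     "between_strain_divergence"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{self.name}: {attr}={v} outside [0, 1]")
        if self.within_strain_mut_rate >= self.between_strain_divergence:
            raise ConfigError(
                f"{self.name}: within_strain_mut_rate must be below "
                f"between_strain_divergence (separability)")

    @property
    def species_token(self) -> str:
        return self.name.split("s__")[-1]


@dataclass(frozen=True)
class CohortConfig:
    """Study design and generative conditions of a synthetic cohort."""

    n_studies: int = 3
    dyads_per_study: int = 30
    infant_timepoints: tuple = (3, 30, 120, 330)
    mother_timepoints: tuple = ((0, "postnatal"), (60, "postnatal"))
    species_pool: tuple = ()
    pathway_map: dict = field(default_factory=dict)  # species name -> {pathway: weight}
    seed: int = 0
    haplotype_length: int = 1000
    n_population_strains: int = 48
    p_csection: float = 0.3
    p_exclusive_bf: float = 0.6
    mother_strain_replacement_prob: float = 0.15
    infant_strain_replacement_prob: float = 0.0
    max_acquisition_day: int = 365

    def validate(self) -> None:
        if self.n_studies < 1 or self.dyads_per_study < 1:
            raise ConfigError("n_studies and dyads_per_study must be >= 1")
        if not self.species_pool:
            raise ConfigError("species pool is empty")
        if any(d < 0 for d in self.infant_timepoints):
            raise ConfigError("infant timepoints must be >= 0")
        for day, scale in self.mother_timepoints:
            if day < 0 or scale not in ("postnatal", "gestational"):
                raise ConfigError(f"bad mother timepoint ({day}, {scale})")
        for p in (self.p_csection, self.p_exclusive_bf,
                  self.mother_strain_replacement_prob,
                  self.infant_strain_replacement_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for spec in self.species_pool:
            spec.validate()


@dataclass
class GroundTruth:
    """What actually happened during generation."""

    transmitted: set  # {(dyad_id, species_name)}
    strain_identity: dict  # (sample_id, species_name) -> lineage label
    transmission_prob: dict  # species name -> configured probability


@dataclass
class Cohort:
    species_table: AbundanceTable
    pathway_table: AbundanceTable
    alignments: dict  # species name -> HaplotypeAlignment
    metadata: pd.DataFrame
    ground_truth: GroundTruth
    config: CohortConfig


_TAXA = [
    ("Bacteria", "Actinobacteria", "Actinobacteria", "Bifidobacteriales",
     "Bifidobacteriaceae", "Bifidobacterium", "Bifidobacterium_longum"),
    ("Bacteria", "Actinobacteria", "Actinobacteria", "Bifidobacteriales",
     "Bifidobacteriaceae", "Bifidobacterium", "Bifidobacterium_bifidum"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
     "Bacteroidaceae", "Bacteroides", "Bacteroides_vulgatus"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
     "Bacteroidaceae", "Bacteroides", "Bacteroides_dorei"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
     "Bacteroidaceae", "Bacteroides", "Bacteroides_fragilis"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
     "Bacteroidaceae", "Bacteroides", "Bacteroides_uniformis"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales",
     "Enterobacteriaceae", "Escherichia", "Escherichia_coli"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
     "Ruminococcaceae", "Ruminococcus", "Ruminococcus_bromii"),
    ("Bacteria", "Firmicutes", "Negativicutes", "Selenomonadales",
     "Veillonellaceae", "Veillonella", "Veillonella_parvula"),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
     "Streptococcaceae", "Streptococcus", "Streptococcus_salivarius"),
    ("Bacteria", "Actinobacteria", "Coriobacteriia", "Coriobacteriales",
     "Coriobacteriaceae", "Collinsella", "Collinsella_aerofaciens"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
     "Tannerellaceae", "Parabacteroides", "Parabacteroides_distasonis"),
]


def taxonomy_string(parts) -> str:
    ranks = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
    return "|".join(pre + p for pre, p in zip(ranks, parts))


def default_species_pool(
    transmission_prob: float = 0.6,
    within_strain_mut_rate: float = 0.001,
    between_strain_divergence: float = 0.05,
    delivery_effect: float = 1.0,
    feeding_effect: float = 1.0,
) -> tuple:
    """Twelve gut species spanning a range of prevalences and abundances."""
    pool = []
    prev_m = [0.9, 0.7, 0.8, 0.6, 0.5, 0.7, 0.8, 0.3, 0.15, 0.2, 0.5, 0.6]
    prev_i = [0.5, 0.4, 0.2, 0.2, 0.2, 0.2, 0.4, 0.2, 0.5, 0.6, 0.2, 0.2]
    logmean = [2.5, 1.5, 2.0, 1.0, 0.5, 1.0, 1.5, 0.5, 0.0, 0.5, 0.0, 0.5]
    for (tax, pm, pi, lm) in zip(_TAXA, prev_m, prev_i, logmean):
        pool.append(SpeciesSpec(
            name=taxonomy_string(tax),
            prevalence_mother=pm, prevalence_infant_base=pi,
            abundance_logmean=lm, abundance_logsd=1.0,
            transmission_prob=transmission_prob,
            within_strain_mut_rate=within_strain_mut_rate,
            between_strain_divergence=between_strain_divergence,
            delivery_effect=delivery_effect, feeding_effect=feeding_effect,
        ))
    return tuple(pool)


def default_pathway_map(species_pool, n_core: int = 10, n_accessory: int = 28,
                        n_per_species: int = 6, seed: int = 7) -> dict:
    """Species -> {pathway: weight} map coupling function to taxonomy.

    Every species carries all ``n_core`` core pathways (so any shared species
    implies many shared pathways) plus a random subset of accessory pathways.
    """
    rng = np.random.default_rng(seed)
    core = [f"PWY-C{i:03d}" for i in range(n_core)]
    accessory = [f"PWY-A{i:03d}" for i in range(n_accessory)]
    pathway_map = {}
    for spec in species_pool:
        chosen = list(rng.choice(accessory, size=min(n_per_species, n_accessory),
                                 replace=False))
        weights = {p: float(w) for p, w in
                   zip(core + chosen, rng.uniform(0.3, 1.5, size=n_core + len(chosen)))}
        pathway_map[spec.name] = weights
    return pathway_map


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    pool = overrides.pop("species_pool", default_species_pool())
    pmap = overrides.pop("pathway_map", default_pathway_map(pool))
    return CohortConfig(species_pool=tuple(pool), pathway_map=pmap, seed=seed,
                        **overrides)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, rate: float, rng) -> np.ndarray:
    """Per-site substitution at ``rate``; mutated sites pick a different base."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n = int(hit.sum())
    if n:
        shift = rng.integers(1, 4, size=n)
        out[hit] = (out[hit] + shift) % 4
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Run the generative model; deterministic in (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = list(config.species_pool)
    n_sp = len(species)
    L = config.haplotype_length
    K = config.n_population_strains

    # population strain pools, one per species
    strain_pool = {}
    for spec in species:
        ancestral = rng.integers(0, 4, size=L)
        strains = np.stack([_mutate(ancestral, spec.between_strain_divergence, rng)
                            for _ in range(K)])
        strain_pool[spec.name] = strains

    max_day = max(config.infant_timepoints) if config.infant_timepoints else 0
    meta_rows = []
    presence: dict[str, list[int]] = {}      # sample -> species indices present
    haplotypes: dict[str, dict[str, np.ndarray]] = {s.name: {} for s in species}
    transmitted: set = set()
    strain_identity: dict = {}

    def lineage(spec_name, idx):
        return f"{spec_name.split('s__')[-1]}|{idx}"

    for s in range(config.n_studies):
        study = f"S{s + 1}"
        for d in range(config.dyads_per_study):
            dyad = f"{study}D{d + 1:03d}"
            mother_subj, infant_subj = f"{dyad}M", f"{dyad}I"
            csection = rng.random() < config.p_csection
            delivery_mode = "cesarean" if csection else "vaginal"
            feeding = "exclusive_bf" if rng.random() < config.p_exclusive_bf \
                else "non_exclusive_bf"
            covs = {
                "delivery_mode": delivery_mode,
                "feeding": feeding,
                "infant_antibiotics": "T" if rng.random() < 0.15 else "F",
                "gestational_age": "full-term" if rng.random() < 0.9 else "preterm",
                "maternal_age_class": str(rng.choice(
                    ["19-29", "30-34", "35-39", "40-50"], p=[0.3, 0.35, 0.25, 0.1])),
                "maternal_abx_before_delivery": "T" if rng.random() < 0.1 else "F",
                "maternal_intrapartum_abx": "T" if rng.random() < 0.2 else "F",
                "birth_weight_class": str(rng.choice(
                    ["low", "normal", "high"], p=[0.08, 0.84, 0.08])),
                "csection_type": (str(rng.choice(["elective", "emergency"]))
                                  if csection else ""),
                "maternal_bmi_class": "owob" if rng.random() < 0.35 else "normal",
                "sex": str(rng.choice(["F", "M"])),
            }

            # mother carriage and base strain
            mother_carries = rng.random(n_sp) < np.array(
                [sp.prevalence_mother for sp in species])
            if not mother_carries.any():
                mother_carries[int(rng.integers(0, n_sp))] = True
            mother_strain = {i: int(rng.integers(0, K))
                             for i in range(n_sp) if mother_carries[i]}

            # transmission / environmental acquisition for the infant
            infant_strain = {}
            acquisition_day = {}
            for i, sp in enumerate(species):
                p_t = sp.transmission_prob * (sp.delivery_effect if csection else 1.0)
                p_env = sp.prevalence_infant_base * (
                    sp.feeding_effect if feeding == "non_exclusive_bf" else 1.0)
                u_t, u_env, u_day = rng.random(), rng.random(), rng.random()
                if mother_carries[i] and u_t < min(p_t, 1.0):
                    base = strain_pool[sp.name][mother_strain[i]]
                    infant_strain[i] = ("transmitted", mother_strain[i],
                                        _mutate(base, sp.within_strain_mut_rate, rng))
                    acquisition_day[i] = 0
                    transmitted.add((dyad, sp.name))
                elif u_env < min(p_env, 1.0):
                    idx = int(rng.integers(0, K))
                    infant_strain[i] = ("environmental", idx,
                                        strain_pool[sp.name][idx].copy())
                    acquisition_day[i] = int(u_day * (config.max_acquisition_day + 1))
            if not infant_strain:
                i = int(rng.integers(0, n_sp))
                idx = int(rng.integers(0, K))
                infant_strain[i] = ("environmental", idx,
                                    strain_pool[species[i].name][idx].copy())
                acquisition_day[i] = 0
            # no stool sample is sterile: the earliest-acquired species must be
            # detectable from the first infant timepoint
            first_tp = min(config.infant_timepoints) if config.infant_timepoints else 0
            if min(acquisition_day.values()) > first_tp:
                earliest = min(acquisition_day, key=lambda i: (acquisition_day[i], i))
                acquisition_day[earliest] = 0

            # mother samples (strain replacement walks across timepoints)
            current = dict(mother_strain)
            for j, (day, scale) in enumerate(config.mother_timepoints):
                sample = f"{mother_subj}_t{j}"
                meta_rows.append({
                    "sample_id": sample, "subject_id": mother_subj, "dyad_id": dyad,
                    "role": "mother", "study_id": study, "day": day,
                    "day_scale": scale, **covs,
                    "sequencing_depth": int(rng.integers(5_000_000, 40_000_000)),
                })
                if j > 0:
                    for i in list(current):
                        if rng.random() < config.mother_strain_replacement_prob:
                            current[i] = int(rng.integers(0, K))
                present = sorted(current)
                presence[sample] = present
                for i in present:
                    sp = species[i]
                    hap = _mutate(strain_pool[sp.name][current[i]],
                                  sp.within_strain_mut_rate, rng)
                    haplotypes[sp.name][sample] = hap
                    strain_identity[(sample, sp.name)] = lineage(sp.name, current[i])

            # infant samples
            current_inf = {i: v for i, v in infant_strain.items()}
            for j, day in enumerate(sorted(config.infant_timepoints)):
                sample = f"{infant_subj}_t{j}"
                meta_rows.append({
                    "sample_id": sample, "subject_id": infant_subj, "dyad_id": dyad,
                    "role": "infant", "study_id": study, "day": day,
                    "day_scale": "postnatal", **covs,
                    "sequencing_depth": int(rng.integers(5_000_000, 40_000_000)),
                })
                if j > 0 and config.infant_strain_replacement_prob > 0:
                    for i in list(current_inf):
                        if rng.random() < config.infant_strain_replacement_prob:
                            origin, _, _ = current_inf[i]
                            idx = int(rng.integers(0, K))
                            current_inf[i] = ("environmental", idx,
                                              strain_pool[species[i].name][idx].copy())
                present = sorted(i for i in current_inf if acquisition_day[i] <= day)
                presence[sample] = present
                for i in present:
                    sp = species[i]
                    origin, idx, seq = current_inf[i]
                    hap = _mutate(seq, sp.within_strain_mut_rate, rng)
                    haplotypes[sp.name][sample] = hap
                    # for transmitted strains idx is the mother's strain index,
                    # so the lineage label matches hers by construction
                    strain_identity[(sample, sp.name)] = lineage(sp.name, idx)

    metadata = pd.DataFrame(meta_rows)

    # abundances: log-normal per present species, columns renormalized to 100
    sample_ids = list(metadata["sample_id"])
    values = np.zeros((n_sp, len(sample_ids)))
    logmeans = np.array([sp.abundance_logmean for sp in species])
    logsds = np.array([sp.abundance_logsd for sp in species])
    for c, sample in enumerate(sample_ids):
        for i in presence[sample]:
            values[i, c] = np.exp(rng.normal(logmeans[i], logsds[i]))
        total = values[:, c].sum()
        values[:, c] = values[:, c] / total * 100.0
    species_names = [sp.name for sp in species]
    species_table = AbundanceTable(
        pd.DataFrame(values, index=species_names, columns=sample_ids),
        "taxon", pd.Series("species", index=species_names))

    # pathways: carrier abundance x per-species weight; community + stratified
    pathway_map = config.pathway_map or default_pathway_map(species)
    all_pwys = sorted({p for w in pathway_map.values() for p in w})
    comm = pd.DataFrame(0.0, index=all_pwys, columns=sample_ids)
    strat_rows = {}
    for i, sp in enumerate(species):
        weights = pathway_map.get(sp.name, {})
        if not weights:
            continue
        genus = sp.name.split("g__")[-1].split("|")[0]
        ab = values[i, :]
        for pwy, w in sorted(weights.items()):
            contrib = ab * w
            comm.loc[pwy] += contrib
            if contrib.any():
                strat_rows[f"{pwy}|g__{genus}.s__{sp.species_token}"] = contrib
    strat = pd.DataFrame(strat_rows, index=sample_ids).T
    pathway_values = pd.concat([comm, strat]).sort_index()
    pathway_table = AbundanceTable(pathway_values, "pathway")

    # alignments (string sequences)
    alignments = {}
    for sp in species:
        recs = {sid: "".join(_BASES[hap]) for sid, hap in haplotypes[sp.name].items()}
        if recs:
            alignments[sp.name] = HaplotypeAlignment(sp.name, recs)

    gt = GroundTruth(
        transmitted=transmitted,
        strain_identity=strain_identity,
        transmission_prob={sp.name: sp.transmission_prob for sp in species},
    )
    return Cohort(species_table, pathway_table, alignments, metadata, gt, config)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write the full file set; returns the path map.

    Emits species table (MetaPhlAn2 merged dialect), pathway table (HUMAnN2
    joined dialect), one aligned FASTA per species, metadata TSV and
    ground-truth TSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": out / "species_abundance.tsv",
        "pathways": out / "pathway_abundance.tsv",
        "metadata": out / "metadata.tsv",
        "transmitted": out / "ground_truth_transmitted.tsv",
        "strains": out / "ground_truth_strains.tsv",
    }
    write_metaphlan_table(cohort.species_table, paths["species"])
    write_humann_pathways(cohort.pathway_table, paths["pathways"])
    write_metadata(cohort.metadata, paths["metadata"])
    gt = cohort.ground_truth
    pd.DataFrame(sorted(gt.transmitted), columns=["dyad_id", "species"]).to_csv(
        paths["transmitted"], sep="\t", index=False)
    pd.DataFrame(
        [(s, sp, lab) for (s, sp), lab in sorted(gt.strain_identity.items())],
        columns=["sample_id", "species", "lineage"],
    ).to_csv(paths["strains"], sep="\t", index=False)
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for name in sorted(cohort.alignments):
        token = name.split("s__")[-1]
        path = aln_dir / f"{token}.aln.fasta"
        write_haplotype_fasta(cohort.alignments[name], path)
        paths[f"alignment:{name}"] = path
    return paths


def load_config_yaml(path) -> CohortConfig:
    """Build a CohortConfig from a YAML file (species specs as mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pool = raw.pop("species_pool", None)
    if pool is not None:
        pool = tuple(SpeciesSpec(**sp) for sp in pool)
    else:
        pool = default_species_pool()
    pmap = raw.pop("pathway_map", None) or default_pathway_map(pool)
    mother_tp = raw.pop("mother_timepoints", None)
    if mother_tp is not None:
        raw["mother_timepoints"] = tuple((int(d), str(s)) for d, s in mother_tp)
    infant_tp = raw.pop("infant_timepoints", None)
    if infant_tp is not None:
        raw["infant_timepoints"] = tuple(int(d) for d in infant_tp)
    return CohortConfig(species_pool=pool, pathway_map=pmap, **raw)
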
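"""Seeded synthetic data emulating a two-condition phosphoproteomics study.

The generator reproduces the statistical structure the downstream stages
assume, with ground-truth labels for every planted signal:

* spectral counts per phosphosite for two diet conditions (HFD vs LFD) with
  a configurable number of biological replicates, Poisson count law, and a
  planted fraction of differential sites changed by a multiplicative fold;
* localization noise -- each PSM is independently assigned a wrong
  neighbouring S/T/Y residue with a controllable probability, and its FLR
  estimate is drawn consistently with its true/false status;
* kinase--substrate prediction tables in two tabular dialects, with planted
  "active" kinases whose substrates concentrate in one direction group;
* an undirected interactome from a planted-partition model split across
  three edge sources (one scored STRING-like table, two SIF files);
* annotation gene sets (GMT) with planted direction associations.

Identical seed and configuration give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError

CONDITIONS = ("HFD", "LFD")
_RESIDUES = np.array(list("STY"))
_RESIDUE_WEIGHTS = np.array([0.65, 0.25, 0.10])
# amino acids used for peptide filler; S/T/Y excluded so the phospho residue
# position within the peptide stays unambiguous
_FILLER_AA = np.array(list("ACDEFGHIKLMNPQRVW"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 2 conditions x 3 biological
    replicates, 200 quantified sites over 76 proteins, expected spectral
    count 10 per site per sample, 10% of sites differential at 4-fold, and
    two 8-node dense interactome modules over a sparse background.
    """

    seed: int = 0
    n_proteins: int = 76
    n_sites: int = 200
    n_replicates_per_condition: int = 3
    baseline_rate: float = 10.0
    frac_differential: float = 0.1
    effect_fold: float = 4.0
    frac_up: float = 0.5
    floc_fraction: float = 0.05
    n_kinases: int = 12
    substrates_per_kinase: int = 30
    n_active_kinases: int = 4
    ppi_modules: tuple[tuple[int, float], ...] = ((8, 0.9), (8, 0.9))
    ppi_background_edge_prob: float = 0.02
    n_terms: int = 20
    genes_per_term: int = 15
    # fraction of an active kinase's substrate quota drawn from its planted
    # direction group
    active_substrate_frac: float = 0.8
    # fraction of non-planted NetworKIN-dialect pairs given sub-threshold scores
    ksr_decoy_low_frac: float = 0.3
    # optional per-site gamma rate multiplier (mean 1, variance = dispersion);
    # None disables over-dispersion
    dispersion: float | None = None

    def validate(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_sites": self.n_sites,
            "n_replicates_per_condition": self.n_replicates_per_condition,
            "n_kinases": self.n_kinases,
            "substrates_per_kinase": self.substrates_per_kinase,
            "n_terms": self.n_terms,
            "genes_per_term": self.genes_per_term,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v}")
        if self.n_active_kinases < 0 or self.n_active_kinases > self.n_kinases:
            raise ConfigurationError("n_active_kinases must lie in [0, n_kinases]")
        fractions = {
            "frac_differential": self.frac_differential,
            "frac_up": self.frac_up,
            "floc_fraction": self.floc_fraction,
            "ppi_background_edge_prob": self.ppi_background_edge_prob,
            "active_substrate_frac": self.active_substrate_frac,
            "ksr_decoy_low_frac": self.ksr_decoy_low_frac,
        }
        for name, v in fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate must be positive")
        if self.effect_fold < 1:
            raise ConfigurationError("effect_fold must be >= 1")
        for size, p in self.ppi_modules:
            if size < 1 or not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"invalid ppi module ({size}, {p})")
        if sum(s for s, _ in self.ppi_modules) > self.n_proteins:
            raise ConfigurationError("ppi module sizes exceed n_proteins")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive or None")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator per simulation component."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass(frozen=True)
class SiteRecord:
    site_id: str
    protein: str
    residue: str
    position: int
    peptide: str


@dataclass
class GroundTruth:
    """Planted-signal labels accompanying every generated table."""

    sites: list[SiteRecord] = field(default_factory=list)
    differential_sites: dict[str, str] = field(default_factory=dict)
    mislocalized_spectra: set[str] = field(default_factory=set)
    active_kinases: dict[str, str] = field(default_factory=dict)
    module_nodes: list[list[str]] = field(default_factory=list)
    term_groups: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sites": [dataclasses.asdict(s) for s in self.sites],
                "differential_sites": self.differential_sites,
                "mislocalized_spectra": sorted(self.mislocalized_spectra),
                "active_kinases": self.active_kinases,
                "module_nodes": self.module_nodes,
                "term_groups": self.term_groups,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            sites=[SiteRecord(**s) for s in d["sites"]],
            differential_sites=d["differential_sites"],
            mislocalized_spectra=set(d["mislocalized_spectra"]),
            active_kinases=d["active_kinases"],
            module_nodes=d["module_nodes"],
            term_groups=d["term_groups"],
        )


def _proteins(config: SimulationConfig) -> list[str]:
    return [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]


def _make_sites(config: SimulationConfig, rng: np.random.Generator) -> list[SiteRecord]:
    proteins = _proteins(config)
    per_protein_rank: dict[str, int] = {}
    sites: list[SiteRecord] = []
    for i in range(config.n_sites):
        protein = proteins[i % len(proteins)]
        rank = per_protein_rank.get(protein, 0)
        per_protein_rank[protein] = rank + 1
        # 10-residue spacing with <5 jitter keeps positions strictly increasing
        position = 10 * (rank + 1) + int(rng.integers(0, 5))
        residue = str(rng.choice(_RESIDUES, p=_RESIDUE_WEIGHTS))
        filler = rng.choice(_FILLER_AA, size=11)
        filler[5] = residue
        peptide = "".join(filler)
        sites.append(
            SiteRecord(
                site_id=f"{protein}:{residue}{position}",
                protein=protein,
                residue=residue,
                position=position,
                peptide=peptide,
            )
        )
    return sites


def simulate_phospho_dataset(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a PSM table with planted differential sites.

    Counts per site and sample follow a Poisson law whose rate is the
    baseline multiplied by ``effect_fold`` (up sites) or ``1/effect_fold``
    (down sites) in the HFD condition.  Each PSM is independently
    mislocalized to a neighbouring S/T/Y decoy residue with probability
    ``floc_fraction``; correctly localized PSMs draw their FLR uniformly
    from [0, 0.01], mislocalized ones from [0.01, 0.5], so the conventional
    1% FLR threshold separates the two populations.
    """
    config.validate()
    rng = config.rng(0)
    truth = truth if truth is not None else GroundTruth()
    sites = _make_sites(config, rng)
    truth.sites = sites

    n_diff = int(round(config.frac_differential * config.n_sites))
    n_up = int(round(config.frac_up * n_diff))
    chosen = rng.choice(config.n_sites, size=n_diff, replace=False)
    truth.differential_sites = {
        sites[int(idx)].site_id: ("up" if j < n_up else "down")
        for j, idx in enumerate(chosen)
    }

    samples = [
        (f"{cond}_{r + 1}", cond)
        for cond in CONDITIONS
        for r in range(config.n_replicates_per_condition)
    ]

    rows: list[tuple] = []
    spectrum_no = 0
    for site in sites:
        rate = config.baseline_rate
        if config.dispersion is not None:
            shape = 1.0 / config.dispersion
            rate *= rng.gamma(shape, 1.0 / shape)
        direction = truth.differential_sites.get(site.site_id)
        for sample_id, cond in samples:
            fold = 1.0
            if cond == "HFD" and direction == "up":
                fold = config.effect_fold
            elif cond == "HFD" and direction == "down":
                fold = 1.0 / config.effect_fold
            count = int(rng.poisson(rate * fold))
            for _ in range(count):
                spectrum_no += 1
                spectrum_id = f"sp{spectrum_no:07d}"
                mislocalized = bool(rng.random() < config.floc_fraction)
                if mislocalized:
                    residue = str(rng.choice(_RESIDUES))
                    offset = int(rng.choice([-2, -1, 1, 2]))
                    position = max(1, site.position + offset)
                    if position == site.position:
                        position = site.position + 3
                    flr = float(rng.uniform(0.01, 0.5))
                    truth.mislocalized_spectra.add(spectrum_id)
                else:
                    residue, position = site.residue, site.position
                    flr = float(rng.uniform(0.0, 0.01))
                rows.append(
                    (
                        spectrum_id,
                        sample_id,
                        cond,
                        site.protein,
                        site.peptide,
                        f"{residue}{position}",
                        round(flr, 6),
                    )
                )
    psm_table = pd.DataFrame(
        rows,
        columns=[
            "spectrum_id",
            "sample_id",
            "condition",
            "protein",
            "peptide",
            "site_list",
            "flr",
        ],
    )
    return psm_table, truth


def simulate_ksr_tables(
    config: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Generate kinase--substrate predictions with planted active kinases.

    Each kinase reports through a single dialect (alternately iGPS-like,
    which carries no scores, and NetworKIN-like, which carries a NetworKIN
    score and NetPhorest probability).  Substrates of planted active kinases
    are preferentially drawn from planted differential sites of the kinase's
    direction; those pairs always receive passing scores, while a
    configurable fraction of decoy NetworKIN pairs falls below both the
    score > 2 and probability > 0.1 filters.  The returned frame keeps
    generation labels (``planted``, ``above_threshold``) that the written
    dialect files omit.
    """
    config.validate()
    if not truth.sites:
        raise ConsistencyError("phospho dataset must be simulated first")
    rng = config.rng(1)
    site_ids = [s.site_id for s in truth.sites]
    by_direction = {
        d: [sid for sid, dd in truth.differential_sites.items() if dd == d]
        for d in ("up", "down")
    }

    kinases = [f"KIN{i:02d}" for i in range(1, config.n_kinases + 1)]
    truth.active_kinases = {}
    rows: list[dict] = []
    for i, kinase in enumerate(kinases):
        source = "igps" if i % 2 == 0 else "networkin"
        active = i < config.n_active_kinases
        direction = None
        if active:
            direction = "up" if i % 2 == 0 else "down"
            truth.active_kinases[kinase] = "HFD" if direction == "up" else "LFD"

        substrates: list[str] = []
        planted_set: set[str] = set()
        if active:
            pool = by_direction[direction]
            quota = int(round(config.active_substrate_frac * config.substrates_per_kinase))
            take = min(quota, len(pool))
            picked = rng.choice(len(pool), size=take, replace=False)
            planted_set = {pool[int(j)] for j in picked}
            substrates.extend(sorted(planted_set))
        remaining = [s for s in site_ids if s not in planted_set]
        n_fill = min(config.substrates_per_kinase - len(substrates), len(remaining))
        fill = rng.choice(len(remaining), size=n_fill, replace=False)
        substrates.extend(remaining[int(j)] for j in fill)

        for sid in substrates:
            planted = sid in planted_set
            if source == "networkin":
                low = (not planted) and bool(rng.random() < config.ksr_decoy_low_frac)
                if low:
                    score = float(rng.uniform(0.2, 1.8))
                    prob = float(rng.uniform(0.0, 0.09))
                else:
                    score = float(rng.uniform(2.5, 8.0))
                    prob = float(rng.uniform(0.05, 0.6))
                rows.append(
                    dict(
                        kinase=kinase,
                        site_id=sid,
                        source=source,
                        networkin_score=round(score, 4),
                        netphorest_probability=round(prob, 4),
                        planted=planted,
                        above_threshold=not low,
                    )
                )
            else:
                rows.append(
                    dict(
                        kinase=kinase,
                        site_id=sid,
                        source=source,
                        networkin_score=np.nan,
                        netphorest_probability=np.nan,
                        planted=planted,
                        above_threshold=True,
                    )
                )
    ksr = pd.DataFrame(rows)
    known = set(site_ids)
    bad = set(ksr["site_id"]) - known
    if bad:
        raise ConsistencyError(f"unknown site ids in KSR table: {sorted(bad)[:5]}")
    return ksr


def simulate_interactome(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Planted-partition interactome split across three edge sources.

    Disjoint dense modules (size and within-module edge probability from
    the configuration) are embedded in a sparse background.  Every edge is
    assigned to a random non-empty subset of {STRING-like, Reactome-like,
    MetaCore-like}; the STRING-like table carries combined scores uniform
    on [0.15, 1.0].
    """
    config.validate()
    rng = config.rng(2)
    truth = truth if truth is not None else GroundTruth()
    proteins = _proteins(config)
    perm = rng.permutation(len(proteins))
    module_of: dict[str, int] = {}
    modules: list[list[str]] = []
    cursor = 0
    for size, _ in config.ppi_modules:
        members = sorted(proteins[int(perm[cursor + j])] for j in range(size))
        for m in members:
            module_of[m] = len(modules)
        modules.append(members)
        cursor += size
    truth.module_nodes = modules

    string_rows, reactome_rows, metacore_rows = [], [], []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a, b = proteins[i], proteins[j]
            ma, mb = module_of.get(a), module_of.get(b)
            if ma is not None and ma == mb:
                p = config.ppi_modules[ma][1]
            else:
                p = config.ppi_background_edge_prob
            if rng.random() >= p:
                continue
            in_string = bool(rng.random() < 0.7)
            in_reactome = bool(rng.random() < 0.5)
            in_metacore = bool(rng.random() < 0.5)
            if not (in_string or in_reactome or in_metacore):
                in_reactome = True
            if in_string:
                string_rows.append((a, b, round(float(rng.uniform(0.15, 1.0)), 4)))
            if in_reactome:
                reactome_rows.append((a, b))
            if in_metacore:
                metacore_rows.append((a, b))

    edges = {
        "string_db": pd.DataFrame(
            string_rows, columns=["node_a", "node_b", "combined_score"]
        ),
        "reactome_fi": pd.DataFrame(reactome_rows, columns=["node_a", "node_b"]),
        "metacore": pd.DataFrame(metacore_rows, columns=["node_a", "node_b"]),
    }
    return edges, truth


def simulate_annotations(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, tuple[str, list[str]]]:
    """GMT-style gene sets with planted direction associations.

    Up to four terms are planted (alternating up/down): their gene lists are
    seeded with the proteins carrying planted differential sites of that
    direction and topped up with random proteins; remaining terms are random
    draws.
    """
    config.validate()
    if not truth.sites:
        raise ConsistencyError("phospho dataset must be simulated first")
    rng = config.rng(3)
    proteins = _proteins(config)
    protein_of = {s.site_id: s.protein for s in truth.sites}
    dir_proteins = {
        d: sorted(
            {
                protein_of[sid]
                for sid, dd in truth.differential_sites.items()
                if dd == d
            }
        )
        for d in ("up", "down")
    }
    n_planted = min(4, config.n_terms) if truth.differential_sites else 0
    truth.term_groups = {}
    annotation: dict[str, tuple[str, list[str]]] = {}
    for t in range(1, config.n_terms + 1):
        term = f"T{t:04d}"
        genes: list[str] = []
        if t <= n_planted:
            direction = "up" if t % 2 == 1 else "down"
            truth.term_groups[term] = direction
            genes.extend(dir_proteins[direction][: config.genes_per_term])
            label = f"planted {direction} process {t}"
        else:
            label = f"background process {t}"
        remaining = [p for p in proteins if p not in set(genes)]
        n_fill = min(config.genes_per_term - len(genes), len(remaining))
        fill = rng.choice(len(remaining), size=n_fill, replace=False)
        genes.extend(remaining[int(j)] for j in sorted(fill))
        annotation[term] = (label, genes)
    return annotation


@dataclass
class SimulatedStudy:
    """All tables of one synthetic study plus its ground truth."""

    config: SimulationConfig
    psms: pd.DataFrame
    ksr: pd.DataFrame
    edges: dict[str, pd.DataFrame]
    annotations: dict[str, tuple[str, list[str]]]
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator with one shared ground truth."""
    psms, truth = simulate_phospho_dataset(config)
    ksr = simulate_ksr_tables(config, truth)
    edges, truth = simulate_interactome(config, truth)
    annotations = simulate_annotations(config, truth)
    return SimulatedStudy(
        config=config,
        psms=psms,
        ksr=ksr,
        edges=edges,
        annotations=annotations,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write all study tables in their on-disk dialects; returns the paths."""
    from . import io as pio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": out / "psms.tsv",
        "ksr_igps": out / "ksr_igps.tsv",
        "ksr_networkin": out / "ksr_networkin.tsv",
        "ppi_string": out / "ppi_string.tsv",
        "ppi_reactome": out / "ppi_reactome.sif",
        "ppi_metacore": out / "ppi_metacore.sif",
        "annotations": out / "annotations.gmt",
        "ground_truth": out / "ground_truth.json",
    }
    study.psms.to_csv(paths["psms"], sep="\t", index=False)
    pio.write_igps_table(study.ksr[study.ksr["source"] == "igps"], paths["ksr_igps"])
    pio.write_networkin_table(
        study.ksr[study.ksr["source"] == "networkin"], paths["ksr_networkin"]
    )
    pio.write_string_table(study.edges["string_db"], paths["ppi_string"])
    pio.write_sif(study.edges["reactome_fi"], paths["ppi_reactome"])
    pio.write_sif(study.edges["metacore"], paths["ppi_metacore"])
    pio.write_gmt(study.annotations, paths["annotations"])
    paths["ground_truth"].write_text(study.truth.to_json())
    return paths
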
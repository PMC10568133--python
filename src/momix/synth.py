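"""Synthetic tri-omic datasets with planted, recoverable group structure.

The generator emulates the study layout the pipeline targets: three dietary
treatment groups (A control, B and C supplemented) sampled at three
timepoints (T0/T1/T2) with 21 metagenomes per group and timepoint.  It
plants the structure the analysis is meant to recover:

* **Taxa** — compositional species profiles drawn per sample from a
  Dirichlet whose mean hits group-specific signature-species targets (e.g.
  *Alistipes* dominating controls at the end of the cycle at 72.38%,
  *Lactobacillus crispatus* at 12.40% in the high-dose group) with a
  sparse, long-tailed Dirichlet background over the remaining mass.
* **Functional pathways** — log-normal background abundances with planted
  log-fold shifts for group-specific pathway sets.
* **NMR latent variables** — standard-normal scores with group mean shifts
  in SD units, each LV carrying a metabolite membership list drawn from the
  bundled compound names.

Effects at T0 run at half strength and at full strength from T1 on, so the
treatment separation is partial at the first sampling and complete later.
A deterministic mini KEGG-like reference (pathways, KOs, genes, reactions,
compounds with synonyms) backs pathway unpacking and enrichment offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GROUPS, TIMEPOINTS, AbundanceTable, LatentVariableMatrix, SampleMetadata
from .kegg import Compound, GeneRecord, MiniKeggFixture, Pathway, Reaction

__all__ = [
    "SyntheticDesign",
    "DesignError",
    "default_design",
    "generate_metadata",
    "generate_taxa_table",
    "generate_pathway_table",
    "generate_lv_matrix",
    "generate_dataset",
    "build_mini_kegg",
    "FIXTURE_PATHWAY_IDS",
]


class DesignError(ValueError):
    """An internally inconsistent synthetic design."""


SIGNATURE_SPECIES = (
    "Alistipes",
    "Bacteroides_fragilis",
    "Lactobacillus_crispatus",
    "Ruminococcus_torques",
    "Subdoligranulum_variabile",
)

FIXTURE_PATHWAY_IDS = (
    "ko00340",  # histidine metabolism
    "ko00250",  # alanine, aspartate and glutamate metabolism
    "ko00562",  # inositol phosphate metabolism
    "ko00230",  # purine metabolism
    "ko00010",  # glycolysis / gluconeogenesis
    "ko00020",  # citrate (TCA) cycle
)


def _default_signatures() -> dict[tuple[str, str, str], float]:
    """Target group-mean relative abundances for the signature species.

    End-of-cycle *Alistipes* means follow the study's printed 72.38 / 5.34 /
    25.87% split across control and the two supplemented groups;
    *L. crispatus* holds 12.40% and *Subdoligranulum* reaches 20.19% in the
    high-dose group from the second sampling; *R. torques* stays near 17%.
    First-sampling targets are set at roughly half strength to emulate the
    partial early separation.
    """
    sig: dict[tuple[str, str, str], float] = {}

    def put(group: str, species: str, t0: float, t1: float, t2: float) -> None:
        sig[(group, "T0", species)] = t0
        sig[(group, "T1", species)] = t1
        sig[(group, "T2", species)] = t2

    put("A", "Alistipes", 0.30, 0.55, 0.7238)
    put("B", "Alistipes", 0.10, 0.0534, 0.0534)
    put("C", "Alistipes", 0.20, 0.2587, 0.2587)
    put("B", "Bacteroides_fragilis", 0.08, 0.16, 0.16)
    put("C", "Lactobacillus_crispatus", 0.062, 0.1240, 0.1240)
    put("C", "Subdoligranulum_variabile", 0.10, 0.2019, 0.15)
    put("C", "Ruminococcus_torques", 0.085, 0.17, 0.17)
    return sig


def _default_planted_pathways() -> dict[str, dict[str, float]]:
    return {
        "B": {"ko00340": 2.5, "ko90007": 2.5, "ko90008": 2.5, "ko90009": 2.5},
        "C": {"ko00562": 2.5, "ko00230": 2.5, "ko90010": 2.5, "ko90011": 2.5},
    }


def _default_lv_metabolites() -> dict[str, set[str]]:
    return {
        "LV1": {"Urocanate", "Xanthine"},
        "LV2": {"myo-Inositol"},
        "LV3": {"L-Alanine", "L-Glutamate"},
        "LV4": {"Lactate"},
        "LV5": {"Acetate"},
        "LV6": {"Formate"},
    }


@dataclass
class SyntheticDesign:
    """Full specification of a synthetic tri-omic study."""

    n_per_group: int = 21
    groups: tuple[str, ...] = GROUPS
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_species: int = 60
    n_pathways: int = 190
    n_lvs: int = 6
    signature_spec: dict[tuple[str, str, str], float] = field(
        default_factory=_default_signatures
    )
    planted_pathways: dict[str, dict[str, float]] = field(
        default_factory=_default_planted_pathways
    )
    lv_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("B", "LV1"): 2.5, ("C", "LV2"): 2.5}
    )
    lv_metabolites: dict[str, set[str]] = field(default_factory=_default_lv_metabolites)
    dirichlet_concentration: float = 0.5
    # per-sample responsiveness to the treatment: planted LV and pathway
    # effects are scaled by a shared 1 + N(0, response_sd) factor per bird,
    # coupling the metabolomic and functional responses as they co-vary in
    # real dose-response data
    response_sd: float = 0.25
    # effect multiplier per timepoint: partial separation early, complete later
    timepoint_strength: dict[str, float] = field(
        default_factory=lambda: {"T0": 0.5, "T1": 1.0, "T2": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_species < 2 or self.n_pathways < 1:
            raise DesignError("population sizes must be positive")
        if self.n_lvs < 1:
            raise DesignError("need at least one latent variable")
        for (g, tp, sp), v in self.signature_spec.items():
            if not np.isfinite(v) or v < 0:
                raise DesignError(f"signature target for {(g, tp, sp)} must be finite >= 0")
            if sp not in self.species_ids():
                raise DesignError(f"signature species {sp!r} not among species ids")
        for g, tp in [(g, tp) for g in self.groups for tp in self.timepoints]:
            total = sum(
                v for (gg, tt, _), v in self.signature_spec.items() if gg == g and tt == tp
            )
            if total >= 1:
                raise DesignError(
                    f"signature targets for group {g} at {tp} sum to {total} >= 1"
                )
        for effects in self.planted_pathways.values():
            for pid, eff in effects.items():
                if pid not in self.pathway_ids():
                    raise DesignError(f"planted pathway {pid!r} not among pathway ids")
                if not np.isfinite(eff):
                    raise DesignError("pathway effect sizes must be finite")
        for lv in self.lv_ids():
            if not self.lv_metabolites.get(lv):
                raise DesignError(f"LV {lv} has an empty metabolite set")

    # -- id spaces ----------------------------------------------------------
    def species_ids(self) -> list[str]:
        n_bg = self.n_species - len(SIGNATURE_SPECIES)
        if n_bg < 1:
            raise DesignError("n_species must exceed the signature species count")
        return list(SIGNATURE_SPECIES) + [
            f"sp_{i:03d}" for i in range(len(SIGNATURE_SPECIES) + 1, self.n_species + 1)
        ]

    def pathway_ids(self) -> list[str]:
        ids = list(FIXTURE_PATHWAY_IDS[: min(self.n_pathways, len(FIXTURE_PATHWAY_IDS))])
        ids += [f"ko{90000 + i:05d}" for i in range(len(ids) + 1, self.n_pathways + 1)]
        return ids

    def lv_ids(self) -> list[str]:
        return [f"LV{i + 1}" for i in range(self.n_lvs)]

    def sample_ids(self, timepoint: str) -> list[str]:
        return [
            f"{g}{i + 1:02d}_{timepoint}"
            for g in self.groups
            for i in range(self.n_per_group)
        ]

    def sample_groups(self, timepoint: str) -> list[str]:
        return [g for g in self.groups for _ in range(self.n_per_group)]

    def planted_features(self, timepoint: str) -> set[str]:
        """Feature ids carrying a planted group effect at this timepoint."""
        if self.timepoint_strength.get(timepoint, 1.0) == 0:
            return set()
        planted = {pid for eff in self.planted_pathways.values() for pid in eff}
        planted |= {lv for (_, lv), e in self.lv_effects.items() if e != 0}
        return planted

    def _rng(self, timepoint: str, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.seed, self.timepoints.index(timepoint), stream]
        )

    def _response(self, timepoint: str) -> np.ndarray:
        """Per-sample treatment responsiveness, shared across omic blocks.

        Planted LV and pathway effects are scaled by the same
        1 + N(0, response_sd) factor per bird, so a strongly responding
        animal shifts in both its metabolome and its functional profile —
        the inter-omic coupling the bi-clustering is designed to exploit.
        """
        n = self.n_per_group * len(self.groups)
        rng = self._rng(timepoint, 4)
        return 1.0 + self.response_sd * rng.normal(0.0, 1.0, size=n)


def default_design(seed: int = 0, **overrides) -> SyntheticDesign:
    return SyntheticDesign(seed=seed, **overrides)


def generate_metadata(design: SyntheticDesign) -> SampleMetadata:
    """Metadata covering every timepoint of the design."""
    sample_ids, group, timepoint = [], {}, {}
    for tp in design.timepoints:
        for sid, g in zip(design.sample_ids(tp), design.sample_groups(tp)):
            sample_ids.append(sid)
            group[sid] = g
            timepoint[sid] = tp
    return SampleMetadata(sample_ids, group, timepoint)


def generate_taxa_table(design: SyntheticDesign, timepoint: str) -> AbundanceTable:
    """Compositional species profiles with signature-species targets.

    Each sample is one Dirichlet draw whose mean puts each signature species
    of the sample's group exactly at its target abundance and spreads the
    remaining mass over a sparse background (concentration
    ``dirichlet_concentration`` per background species), so empirical group
    means converge to the targets and every row sums to one.
    """
    rng = design._rng(timepoint, 1)
    species = design.species_ids()
    rows = []
    for g in design.groups:
        targets = {
            sp: v
            for (gg, tt, sp), v in design.signature_spec.items()
            if gg == g and tt == timepoint
        }
        t_sum = sum(targets.values())
        bg = [sp for sp in species if sp not in targets]
        a_bg = design.dirichlet_concentration
        alpha = np.full(len(species), a_bg)
        total_bg = a_bg * len(bg)
        for i, sp in enumerate(species):
            if sp in targets:
                alpha[i] = total_bg * targets[sp] / (1.0 - t_sum)
        rows.append(rng.dirichlet(alpha, size=design.n_per_group))
    values = np.vstack(rows)
    return AbundanceTable(design.sample_ids(timepoint), species, values, "TAXON")


def generate_pathway_table(design: SyntheticDesign, timepoint: str) -> AbundanceTable:
    """Log-normal pathway abundances with planted group log-fold shifts."""
    rng = design._rng(timepoint, 2)
    pathways = design.pathway_ids()
    strength = design.timepoint_strength.get(timepoint, 1.0)
    n = design.n_per_group * len(design.groups)
    response = design._response(timepoint)
    log_values = rng.normal(0.0, 1.0, size=(n, len(pathways)))
    col = {pid: j for j, pid in enumerate(pathways)}
    for gi, g in enumerate(design.groups):
        sl = slice(gi * design.n_per_group, (gi + 1) * design.n_per_group)
        for pid, eff in design.planted_pathways.get(g, {}).items():
            log_values[sl, col[pid]] += eff * strength * response[sl]
    return AbundanceTable(
        design.sample_ids(timepoint), pathways, np.exp(log_values), "PATHWAY"
    )


def generate_lv_matrix(design: SyntheticDesign, timepoint: str) -> LatentVariableMatrix:
    """Standard-normal LV scores with group mean shifts in SD units."""
    rng = design._rng(timepoint, 3)
    lvs = design.lv_ids()
    strength = design.timepoint_strength.get(timepoint, 1.0)
    n = design.n_per_group * len(design.groups)
    response = design._response(timepoint)
    scores = rng.normal(0.0, 1.0, size=(n, len(lvs)))
    col = {lv: j for j, lv in enumerate(lvs)}
    for gi, g in enumerate(design.groups):
        sl = slice(gi * design.n_per_group, (gi + 1) * design.n_per_group)
        for (gg, lv), eff in design.lv_effects.items():
            if gg == g:
                scores[sl, col[lv]] += eff * strength * response[sl]
    return LatentVariableMatrix(
        design.sample_ids(timepoint),
        lvs,
        scores,
        {lv: set(design.lv_metabolites[lv]) for lv in lvs},
    )


def write_dataset(design: SyntheticDesign, outdir) -> None:
    """Write the full synthetic dataset in the pipeline's on-disk formats.

    Produces ``metadata.tsv``, ``reference.json`` and per-timepoint
    ``taxa_<tp>.tsv`` / ``pathways_<tp>.tsv`` / ``lv_<tp>.tsv`` (+ LV
    membership sidecar) — exactly the layout ``run_all`` consumes.
    """
    from pathlib import Path

    from .io import write_abundance_table, write_lv_matrix, write_metadata
    from .kegg import save_reference

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta, data = generate_dataset(design)
    write_metadata(meta, outdir / "metadata.tsv")
    save_reference(build_mini_kegg(), outdir / "reference.json")
    for tp, tables in data.items():
        write_abundance_table(tables["taxa"], outdir / f"taxa_{tp}.tsv")
        write_abundance_table(tables["pathways"], outdir / f"pathways_{tp}.tsv")
        write_lv_matrix(tables["lv"], outdir / f"lv_{tp}.tsv")


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[SampleMetadata, dict[str, dict[str, object]]]:
    """All per-timepoint tables plus metadata, keyed timepoint -> block."""
    meta = generate_metadata(design)
    data: dict[str, dict[str, object]] = {}
    for tp in design.timepoints:
        data[tp] = {
            "taxa": generate_taxa_table(design, tp),
            "pathways": generate_pathway_table(design, tp),
            "lv": generate_lv_matrix(design, tp),
        }
    return meta, data


# ---------------------------------------------------------------------------
# mini KEGG-like reference fixture


def build_mini_kegg() -> MiniKeggFixture:
    """Deterministic offline KEGG-like reference store.

    Contains six pathways (histidine; alanine/aspartate/glutamate; inositol
    phosphate; purine; glycolysis/gluconeogenesis; TCA cycle), the key
    reactions linking the study's NMR-observed metabolites to them —
    including both urocanate-producing reactions R01168 and R02914 — and a
    KO -> gene-symbol/ENTREZ map.  Where no public identifier is implied by
    the reaction chemistry, KO ids, gene symbols and ENTREZ ids are
    synthetic placeholders; the store is a synthetic stand-in for a licensed
    KEGG mirror, adequate for offline pipeline runs and tests.
    """
    compounds = {
        "C00001": Compound("C00001", "Water", ["H2O"]),
        "C00007": Compound("C00007", "Oxygen", ["O2"]),
        "C00003": Compound("C00003", "NAD+", ["NAD"]),
        "C00004": Compound("C00004", "NADH", []),
        "C00009": Compound("C00009", "Orthophosphate", ["phosphate", "Pi"]),
        "C00014": Compound("C00014", "Ammonia", ["NH3"]),
        "C00022": Compound("C00022", "Pyruvate", ["pyruvic acid"]),
        "C00025": Compound("C00025", "L-Glutamate", ["glutamate", "glutamic acid"]),
        "C00026": Compound("C00026", "2-Oxoglutarate", ["alpha-ketoglutarate"]),
        "C00027": Compound("C00027", "Hydrogen peroxide", ["H2O2"]),
        "C00033": Compound("C00033", "Acetate", ["acetic acid", "acetate ion"]),
        "C00041": Compound("C00041", "L-Alanine", ["alanine"]),
        "C00049": Compound("C00049", "Aspartate", ["L-Aspartate", "aspartic acid"]),
        "C00058": Compound("C00058", "Formate", ["formic acid", "methanoate"]),
        "C00135": Compound("C00135", "L-Histidine", ["histidine"]),
        "C00137": Compound("C00137", "myo-Inositol", ["inositol", "meso-inositol"]),
        "C00186": Compound("C00186", "Lactate", ["L-Lactate", "lactic acid"]),
        "C00246": Compound("C00246", "Butyrate", ["butanoate", "butanoic acid"]),
        "C00253": Compound("C00253", "Nicotinate", ["niacin", "nicotinic acid"]),
        "C00262": Compound("C00262", "Hypoxanthine", []),
        "C00385": Compound("C00385", "Xanthine", []),
        "C00785": Compound("C00785", "Urocanate", ["urocanic acid"]),
        "C01011": Compound("C01011", "N-Formyl-L-aspartate", []),
        "C01177": Compound("C01177", "Inositol 1-phosphate", ["1D-myo-inositol 1-phosphate"]),
        "C01272": Compound("C01272", "myo-Inositol 4-phosphate", ["1D-myo-inositol 4-phosphate"]),
        "C03680": Compound("C03680", "4-Imidazolone-5-propanoate", []),
        "C00024": Compound("C00024", "Acetyl-CoA", []),
        "C00010": Compound("C00010", "CoA", ["coenzyme A"]),
        "C00002": Compound("C00002", "ATP", []),
        "C00020": Compound("C00020", "AMP", []),
        "C00013": Compound("C00013", "Diphosphate", ["pyrophosphate", "PPi"]),
    }

    reactions = {
        # histidine metabolism: two independent urocanate-producing routes
        "R01168": Reaction(
            "R01168",
            "L-histidine ammonia-lyase",
            substrates=["C00135"],
            products=["C00785", "C00014"],  # Urocanate + Ammonia
            enzyme_ec="4.3.1.3",
            kos=["K01745"],
        ),
        "R02914": Reaction(
            "R02914",
            "4,5-Dihydro-4-oxo-5-imidazolepropanoate hydro-lyase",
            substrates=["C03680"],
            products=["C00785", "C00001"],  # Urocanate + Water
            enzyme_ec="4.2.1.49",
            kos=["K01712"],
        ),
        # alanine, aspartate and glutamate metabolism
        "R00526": Reaction(
            "R00526",
            "N-Formyl-L-aspartate amidohydrolase",
            substrates=["C01011", "C00001"],
            products=["C00049", "C00058"],  # Aspartate + Formate
            enzyme_ec="3.5.1.8",
            kos=["K06016"],
        ),
        "R00258": Reaction(
            "R00258",
            "L-Alanine:2-oxoglutarate aminotransferase",
            substrates=["C00041", "C00026"],
            products=["C00022", "C00025"],  # Pyruvate + L-Glutamate
            enzyme_ec="2.6.1.2",
            kos=["K00814"],
        ),
        # inositol phosphate metabolism: both phosphohydrolases yield myo-inositol
        "R01185": Reaction(
            "R01185",
            "1D-myo-inositol 1-phosphate phosphohydrolase",
            substrates=["C01177", "C00001"],
            products=["C00137", "C00009"],  # myo-Inositol + Orthophosphate
            enzyme_ec="3.1.3.25",
            kos=["K01092"],
        ),
        "R01186": Reaction(
            "R01186",
            "1D-myo-inositol 4-phosphate phosphohydrolase",
            substrates=["C01272", "C00001"],
            products=["C00137", "C00009"],
            enzyme_ec="3.1.3.25",
            kos=["K01092"],
        ),
        # purine metabolism
        "R01769": Reaction(
            "R01769",
            "hypoxanthine:oxygen oxidoreductase",
            substrates=["C00262", "C00001", "C00007"],
            products=["C00385", "C00027"],  # Xanthine + H2O2
            enzyme_ec="1.17.3.2",
            kos=["K00106"],
        ),
        # glycolysis / gluconeogenesis
        "R00703": Reaction(
            "R00703",
            "L-lactate:NAD+ oxidoreductase",
            substrates=["C00186", "C00003"],
            products=["C00022", "C00004"],  # Pyruvate + NADH
            enzyme_ec="1.1.1.27",
            kos=["K00016"],
        ),
        # acetate activation feeding the TCA cycle
        "R00235": Reaction(
            "R00235",
            "acetate:CoA ligase",
            substrates=["C00033", "C00010", "C00002"],
            products=["C00024", "C00020", "C00013"],
            enzyme_ec="6.2.1.1",
            kos=["K01895"],
        ),
    }

    # KO -> gene map: key enzymes carry public-style symbols; the rest are
    # synthetic placeholder orthologs padding each pathway.
    key_genes = {
        "K01745": ("HAL", 3034),
        "K01712": ("UROC1", 131669),
        "K06016": ("nfdA", None),
        "K00814": ("GPT", 2875),
        "K01092": ("IMPA1", 3612),
        "K00106": ("XDH", 7498),
        "K00016": ("LDHA", 3939),
        "K01895": ("ACSS2", 55902),
    }
    ko_genes = {
        ko: GeneRecord(ko, symbol, entrez) for ko, (symbol, entrez) in key_genes.items()
    }

    pathway_defs = {
        "ko00340": ("Histidine metabolism", ["R01168", "R02914"], ["K01745", "K01712"]),
        "ko00250": (
            "Alanine, aspartate and glutamate metabolism",
            ["R00526", "R00258"],
            ["K06016", "K00814"],
        ),
        "ko00562": ("Inositol phosphate metabolism", ["R01185", "R01186"], ["K01092"]),
        "ko00230": ("Purine metabolism", ["R01769"], ["K00106"]),
        "ko00010": ("Glycolysis / Gluconeogenesis", ["R00703"], ["K00016"]),
        "ko00020": ("Citrate cycle (TCA cycle)", ["R00235"], ["K01895"]),
    }
    pathways: dict[str, Pathway] = {}
    filler_idx = 1
    for pid, (name, rxns, kos) in pathway_defs.items():
        kos = list(kos)
        # pad each pathway with five synthetic placeholder orthologs
        for _ in range(5):
            ko = f"K9{filler_idx:04d}"
            symbol = f"{pid[2:]}_g{filler_idx:02d}"
            entrez = 900000 + filler_idx if filler_idx % 3 else None
            ko_genes[ko] = GeneRecord(ko, symbol, entrez)
            kos.append(ko)
            filler_idx += 1
        pathways[pid] = Pathway(pid, name, kos, list(rxns))

    fixture = MiniKeggFixture(pathways, ko_genes, reactions, compounds)
    fixture.validate()
    return fixture
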
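"""Offline KEGG-like reference store.

Functional-pathway abundances arrive as pathway-level features; to feed a
pathway-enrichment network model they must be unpacked to gene level
(KEGG ortholog -> gene symbol, ENTREZ id when available) and metabolite
names coming from NMR latent variables must be resolved against compound
synonyms.  All of that is served from an offline JSON-serializable store so
the whole pipeline is a pure function of its inputs; live KEGG REST access
is an explicit opt-in that caches into the same store.
"""

from __future__ import annotations

import json
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "GeneRecord",
    "CompoundResolution",
    "Pathway",
    "Reaction",
    "Compound",
    "MiniKeggFixture",
    "unpack_pathway",
    "resolve_metabolites",
    "fetch_live_pathway",
    "load_reference",
    "save_reference",
    "UnknownPathwayError",
    "OfflineModeError",
]

_KO_RE = re.compile(r"^K\d{5}$")


class UnknownPathwayError(KeyError):
    """Raised when a pathway id is not present in the reference store."""


class OfflineModeError(RuntimeError):
    """Raised when a live KEGG fetch is requested while networking is disabled."""


@dataclass(frozen=True)
class GeneRecord:
    """A KEGG ortholog resolved to a gene symbol (and ENTREZ id when mapped)."""

    ko_id: str
    gene_symbol: str
    entrez_id: int | None = None

    def __post_init__(self) -> None:
        if not _KO_RE.match(self.ko_id):
            raise ValueError(f"KO id {self.ko_id!r} does not match K + 5 digits")
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")


@dataclass(frozen=True)
class CompoundResolution:
    """Outcome of matching a free-text metabolite name against the store."""

    query_name: str
    compound_id: str | None
    matched_synonym: str | None
    status: str  # resolved | ambiguous | unresolved
    candidates: tuple[str, ...] = ()


@dataclass
class Pathway:
    pathway_id: str
    name: str
    kos: list[str]
    reactions: list[str] = field(default_factory=list)


@dataclass
class Reaction:
    reaction_id: str
    name: str
    substrates: list[str]  # compound ids
    products: list[str]  # compound ids
    enzyme_ec: str
    kos: list[str] = field(default_factory=list)


@dataclass
class Compound:
    compound_id: str
    name: str
    synonyms: list[str] = field(default_factory=list)


def _norm(name: str) -> str:
    """Case-fold and collapse whitespace/hyphen runs for synonym matching."""
    return re.sub(r"[\s\-_]+", " ", name.strip()).casefold()


@dataclass
class MiniKeggFixture:
    """Self-contained pathway/KO/gene/reaction/compound reference.

    Every reaction's compounds and KOs must resolve within the store;
    :meth:`validate` enforces this closure so downstream network
    construction can assume referential integrity.
    """

    pathways: dict[str, Pathway]
    ko_genes: dict[str, GeneRecord]
    reactions: dict[str, Reaction]
    compounds: dict[str, Compound]

    def validate(self) -> None:
        for rx in self.reactions.values():
            for cid in list(rx.substrates) + list(rx.products):
                if cid not in self.compounds:
                    raise ValueError(
                        f"reaction {rx.reaction_id} cites unknown compound {cid!r}"
                    )
            for ko in rx.kos:
                if ko not in self.ko_genes:
                    raise ValueError(
                        f"reaction {rx.reaction_id} cites unknown KO {ko!r}"
                    )
        for pw in self.pathways.values():
            for rid in pw.reactions:
                if rid not in self.reactions:
                    raise ValueError(
                        f"pathway {pw.pathway_id} cites unknown reaction {rid!r}"
                    )

    # -- compound name index ------------------------------------------------
    def _name_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {}
        for comp in self.compounds.values():
            for nm in [comp.name, *comp.synonyms]:
                idx.setdefault(_norm(nm), set()).add(comp.compound_id)
        return idx

    def compound_name(self, compound_id: str) -> str:
        return self.compounds[compound_id].name

    def pathway_compounds(self, pathway_id: str) -> set[str]:
        """Compound ids touched by any reaction of the pathway."""
        pw = self.pathways[pathway_id]
        out: set[str] = set()
        for rid in pw.reactions:
            rx = self.reactions[rid]
            out.update(rx.substrates)
            out.update(rx.products)
        return out

    def pathway_genes(self, pathway_id: str) -> set[str]:
        pw = self.pathways[pathway_id]
        return {
            self.ko_genes[ko].gene_symbol for ko in pw.kos if ko in self.ko_genes
        }

    def to_dict(self) -> dict:
        return {
            "pathways": {
                pid: {"name": p.name, "kos": p.kos, "reactions": p.reactions}
                for pid, p in sorted(self.pathways.items())
            },
            "ko_genes": {
                ko: {"gene_symbol": g.gene_symbol, "entrez_id": g.entrez_id}
                for ko, g in sorted(self.ko_genes.items())
            },
            "reactions": {
                rid: {
                    "name": r.name,
                    "substrates": r.substrates,
                    "products": r.products,
                    "enzyme_ec": r.enzyme_ec,
                    "kos": r.kos,
                }
                for rid, r in sorted(self.reactions.items())
            },
            "compounds": {
                cid: {"name": c.name, "synonyms": c.synonyms}
                for cid, c in sorted(self.compounds.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MiniKeggFixture":
        fix = cls(
            pathways={
                pid: Pathway(pid, v["name"], list(v["kos"]), list(v.get("reactions", [])))
                for pid, v in d["pathways"].items()
            },
            ko_genes={
                ko: GeneRecord(ko, v["gene_symbol"], v.get("entrez_id"))
                for ko, v in d["ko_genes"].items()
            },
            reactions={
                rid: Reaction(
                    rid,
                    v["name"],
                    list(v["substrates"]),
                    list(v["products"]),
                    v["enzyme_ec"],
                    list(v.get("kos", [])),
                )
                for rid, v in d["reactions"].items()
            },
            compounds={
                cid: Compound(cid, v["name"], list(v.get("synonyms", [])))
                for cid, v in d["compounds"].items()
            },
        )
        fix.validate()
        return fix


def save_reference(ref: MiniKeggFixture, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ref.to_dict(), indent=1, sort_keys=True))


def load_reference(path: str | Path) -> MiniKeggFixture:
    return MiniKeggFixture.from_dict(json.loads(Path(path).read_text()))


def unpack_pathway(
    pathway_id: str, ref: MiniKeggFixture
) -> tuple[list[GeneRecord], list[str]]:
    """Unpack a functional pathway to gene level.

    Returns one :class:`GeneRecord` per KO of the pathway (ordered by KO id)
    plus the side list of KOs for which the store has no gene symbol —
    partial mapping is expected and must remain auditable, never silently
    dropped.
    """
    if pathway_id not in ref.pathways:
        raise UnknownPathwayError(f"pathway {pathway_id!r} not in reference store")
    records: list[GeneRecord] = []
    skipped: list[str] = []
    for ko in sorted(ref.pathways[pathway_id].kos):
        rec = ref.ko_genes.get(ko)
        if rec is None:
            skipped.append(ko)
        else:
            records.append(rec)
    return records, skipped


def resolve_metabolites(
    names: Iterable[str], ref: MiniKeggFixture
) -> list[CompoundResolution]:
    """Resolve free-text metabolite names against canonical names and synonyms.

    Matching is exact after case-folding and whitespace/hyphen normalization;
    no fuzzy matching, and ambiguity (two compounds sharing a synonym) is
    reported, never auto-resolved.
    """
    idx = ref._name_index()
    out: list[CompoundResolution] = []
    for name in names:
        hits = sorted(idx.get(_norm(name), ()))
        if len(hits) == 1:
            cid = hits[0]
            comp = ref.compounds[cid]
            matched = next(
                (nm for nm in [comp.name, *comp.synonyms] if _norm(nm) == _norm(name)),
                comp.name,
            )
            out.append(CompoundResolution(name, cid, matched, "resolved", tuple(hits)))
        elif len(hits) >= 2:
            out.append(CompoundResolution(name, None, None, "ambiguous", tuple(hits)))
        else:
            out.append(CompoundResolution(name, None, None, "unresolved", ()))
    return out


_KEGG_REST = "https://rest.kegg.jp"


def fetch_live_pathway(
    pathway_id: str,
    *,
    online: bool = False,
    cache_dir: str | Path | None = None,
    _opener=None,
) -> Pathway:
    """Fetch a pathway's KO list from the public KEGG REST flat-file API.

    Offline mode (the default) never touches the network and raises
    :class:`OfflineModeError`.  Successful fetches are cached to
    ``cache_dir`` so a second call is served byte-identically from disk.
    """
    if cache_dir is not None:
        cached = Path(cache_dir) / f"{pathway_id}.json"
        if cached.exists():
            d = json.loads(cached.read_text())
            return Pathway(d["pathway_id"], d["name"], list(d["kos"]))
    if not online:
        raise OfflineModeError(
            "live KEGG access is disabled; pass online=True or use the offline "
            "reference store"
        )
    opener = _opener or (lambda url: urllib.request.urlopen(url, timeout=30).read().decode())
    try:
        text = opener(f"{_KEGG_REST}/link/ko/{pathway_id}")
        name_text = opener(f"{_KEGG_REST}/list/{pathway_id}")
    except OfflineModeError:
        raise
    except Exception as exc:  # pragma: no cover - network paths
        raise OfflineModeError(
            f"KEGG fetch failed ({exc}); use the offline fixture instead"
        ) from exc
    kos = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[1].startswith("ko:"):
            raise ValueError(f"malformed KEGG link flat-file at line {lineno}: {line!r}")
        kos.append(parts[1][3:])
    name = name_text.split("\t")[1].strip() if "\t" in name_text else pathway_id
    pw = Pathway(pathway_id, name, sorted(set(kos)))
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        (Path(cache_dir) / f"{pathway_id}.json").write_text(
            json.dumps(
                {"pathway_id": pw.pathway_id, "name": pw.name, "kos": pw.kos},
                sort_keys=True,
            )
        )
    return pw
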
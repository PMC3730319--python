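"""KGML-subset parsing and the metabolome/transcriptome pathway network.

Pathways are identified by KEGG map accession.  The quantified metabolite
panel hits a pathway through shared compound IDs; the up-regulated gene
list hits a pathway through a static gene-to-enzyme map (replacing an
online ID-conversion service).  The pathway-pathway network links two
pathways when they share mapped compounds or mapped enzymes, with the
shared-entity count as the edge weight; a flag widens counting to all KGML
entities for the global-map variant.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd
from lxml import etree

from .errors import MalformedXMLError, UnknownFormatError

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PathwayRecord:
    pathway_id: str
    name: str
    compounds: frozenset[str]
    enzymes: frozenset[str]
    reactions: frozenset[tuple[tuple[str, ...], tuple[str, ...], str]]


@dataclasses.dataclass
class GeneMap:
    """Rows of (input gene ID, entrez ID, enzyme identifier)."""

    rows: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        seen = set()
        for inp, _, ez in self.rows:
            if (inp, ez) in seen:
                raise ValueError(f"duplicate (input, enzyme) row: {(inp, ez)}")
            seen.add((inp, ez))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(tuple(df.itertuples(index=False, name=None)))

    def enzymes_for(self, gene: str) -> tuple[str, ...]:
        # accession prefixes (ec:, cpd:) are stripped to match parsed records
        return tuple(_strip_prefix(ez) for inp, _, ez in self.rows if inp == gene)


def _strip_prefix(name: str) -> str:
    return name.split(":", 1)[1] if ":" in name else name


def parse_kgml(files) -> list[PathwayRecord]:
    """Parse KGML-subset files into pathway records.

    Consumes ``entry`` elements of type compound/enzyme and ``reaction``
    elements with substrate/product children; unknown elements are ignored
    with a logged warning.  A reaction referencing an undeclared compound or
    enzyme raises MalformedXMLError naming the ID.
    """
    records = []
    for path in files:
        path = Path(path)
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise MalformedXMLError(f"{path}: {exc}") from exc
        root = tree.getroot()
        pid = _strip_prefix(root.get("name", path.stem))
        compounds, enzymes, reactions = set(), set(), set()
        for el in root:
            if el.tag == "entry":
                etype = el.get("type")
                ename = _strip_prefix(el.get("name", ""))
                if not ename:
                    raise MalformedXMLError(f"{path}: entry with empty name")
                if etype == "compound":
                    compounds.add(ename)
                elif etype in ("enzyme", "gene", "ortholog"):
                    enzymes.add(ename)
                else:
                    log.warning("%s: ignoring entry of type %r", path, etype)
            elif el.tag == "reaction":
                subs = tuple(
                    sorted(_strip_prefix(c.get("name", "")) for c in el if c.tag == "substrate")
                )
                prods = tuple(
                    sorted(_strip_prefix(c.get("name", "")) for c in el if c.tag == "product")
                )
                enzyme = _strip_prefix(el.get("enzyme", ""))
                for cid in subs + prods:
                    if cid not in compounds:
                        raise MalformedXMLError(
                            f"{path}: reaction references undeclared compound {cid}"
                        )
                if enzyme and enzyme not in enzymes:
                    raise MalformedXMLError(
                        f"{path}: reaction references undeclared enzyme {enzyme}"
                    )
                reactions.add((subs, prods, enzyme))
            else:
                log.warning("%s: ignoring element %r", path, el.tag)
        records.append(
            PathwayRecord(pid, root.get("title", pid), frozenset(compounds), frozenset(enzymes), frozenset(reactions))
        )
    return records


def map_genes(
    genes, gmap: GeneMap, pathways: list[PathwayRecord]
) -> set[tuple[str, str]]:
    """Gene list -> enzymes -> (pathway, enzyme) hits; unmapped genes warn."""
    hits: set[tuple[str, str]] = set()
    for gene in genes:
        enzymes = gmap.enzymes_for(gene)
        if not enzymes:
            log.info("gene %s has no enzyme mapping", gene)
            continue
        found = False
        for ez in enzymes:
            for rec in pathways:
                if ez in rec.enzymes:
                    hits.add((rec.pathway_id, ez))
                    found = True
        if not found:
            warnings.warn(f"gene {gene} maps to enzymes absent from every pathway")
    return hits


def map_metabolites(panel, pathways: list[PathwayRecord]) -> set[tuple[str, str]]:
    """Panel of (metabolite name, compound ID) -> (pathway, compound) hits."""
    hits = set()
    for _, cid in panel:
        for rec in pathways:
            if cid in rec.compounds:
                hits.add((rec.pathway_id, cid))
    return hits


def compare_sets(met_pathways: set[str], trans_pathways: set[str]) -> dict[str, set[str]]:
    """Exact partition into common / metabolome-only / transcriptome-only."""
    return {
        "common": met_pathways & trans_pathways,
        "metabolome_only": met_pathways - trans_pathways,
        "transcriptome_only": trans_pathways - met_pathways,
    }


def comparison_report(
    records: list[PathwayRecord], met_pathways: set[str], trans_pathways: set[str]
) -> pd.DataFrame:
    """Two-column checkmark table of pathway membership per omics source."""
    rows = []
    for rec in records:
        in_m, in_t = rec.pathway_id in met_pathways, rec.pathway_id in trans_pathways
        if in_m or in_t:
            rows.append(
                {
                    "pathway_id": rec.pathway_id,
                    "pathway": rec.name,
                    "metabolome": "V" if in_m else "",
                    "transcriptome": "V" if in_t else "",
                }
            )
    return pd.DataFrame(rows)


def build_graph(
    records: list[PathwayRecord],
    met_hits: set[tuple[str, str]],
    trans_hits: set[tuple[str, str]],
    all_entities: bool = False,
) -> nx.Graph:
    """Pathway-pathway network weighted by shared compounds plus enzymes.

    Nodes are the hit pathways, tagged ``source`` in {metabolome,
    transcriptome, both}.  By default only mapped entities (panel compounds,
    gene-mapped enzymes) count toward edge weights; ``all_entities=True``
    counts every KGML compound and enzyme instead.
    """
    met_p = {p for p, _ in met_hits}
    trans_p = {p for p, _ in trans_hits}
    by_id = {r.pathway_id: r for r in records}
    mapped_compounds = {c for _, c in met_hits}
    mapped_enzymes = {e for _, e in trans_hits}

    g = nx.Graph()
    for pid in sorted(met_p | trans_p):
        source = "both" if pid in met_p and pid in trans_p else (
            "metabolome" if pid in met_p else "transcriptome"
        )
        g.add_node(pid, source=source, name=by_id[pid].name if pid in by_id else pid)

    nodes = sorted(g.nodes)
    for i, p in enumerate(nodes):
        for q in nodes[i + 1 :]:
            rp, rq = by_id.get(p), by_id.get(q)
            if rp is None or rq is None:
                continue
            comp = rp.compounds & rq.compounds
            enz = rp.enzymes & rq.enzymes
            if not all_entities:
                comp &= mapped_compounds
                enz &= mapped_enzymes
            w = len(comp) + len(enz)
            if w >= 1:
                g.add_edge(p, q, weight=w)
    return g


def export_graph(g: nx.Graph, path: str | Path, format: str | None = None) -> Path:
    """Write the network as GraphML or SIF (format inferred from suffix)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\tshares_{data.get('weight', 1)}\t{v}\n")
            for n in sorted(g.nodes):
                if g.degree(n) == 0:
                    fh.write(f"{n}\n")
    else:
        raise UnknownFormatError(fmt)
    return path


def read_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(path)
    # GraphML stores weights as written; normalize to int for round-tripping
    for _, _, data in g.edges(data=True):
        if "weight" in data:
            data["weight"] = int(data["weight"])
    return g
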
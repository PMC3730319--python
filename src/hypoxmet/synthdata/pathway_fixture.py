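"""Synthetic KGML-subset pathway fixture for the multi-omics comparison.

Writes one KGML-flavored XML file per pathway in the published two-column
membership table (14 pathways reachable from the quantified metabolite panel,
11 from the up-regulated gene set, 4 in common), plus a 66-entry mock
up-regulated gene list and the static gene-to-enzyme map that stands in for
an online ID-conversion service.

Compound accessions are real KEGG IDs and the mapped enzymes are realistic
(pyruvate kinase EC 2.7.1.40 sits in glycolysis, purine and pyruvate
metabolism; cytosolic phospholipase A2 bridges the two lipid pathways), but
the exact membership beyond the published column structure is synthetic.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .templates import default_library

#: Table rows: (pathway id, display name, in metabolome set, in transcriptome set).
PATHWAY_MEMBERSHIP: tuple[tuple[str, str, bool, bool], ...] = (
    ("map00010", "Glycolysis / Gluconeogenesis", True, True),
    ("map00230", "Purine metabolism", True, True),
    ("map00330", "Arginine and proline metabolism", True, True),
    ("map00620", "Pyruvate metabolism", True, True),
    ("map00040", "Pentose and glucuronate interconversions", True, False),
    ("map00053", "Ascorbate and aldarate metabolism", True, False),
    ("map00250", "Alanine, aspartate and glutamate metabolism", True, False),
    ("map00260", "Glycine, serine and threonine metabolism", True, False),
    ("map00270", "Cysteine and methionine metabolism", True, False),
    ("map00290", "Valine, leucine and isoleucine biosynthesis", True, False),
    ("map00430", "Taurine and hypotaurine metabolism", True, False),
    ("map00471", "D-Glutamine and D-glutamate metabolism", True, False),
    ("map00480", "Glutathione metabolism", True, False),
    ("map00910", "Nitrogen metabolism", True, False),
    ("map00051", "Fructose and mannose metabolism", False, True),
    ("map00072", "Synthesis and degradation of ketone bodies", False, True),
    ("map00590", "Arachidonic acid metabolism", False, True),
    ("map00591", "Linoleic acid metabolism", False, True),
    ("map00830", "Retinol metabolism", False, True),
    ("map00980", "Metabolism of xenobiotics by cytochrome P450", False, True),
    ("map00982", "Drug metabolism - cytochrome P450", False, True),
)

_COMPOUNDS: dict[str, tuple[str, ...]] = {
    "map00010": ("C00031", "C00022", "C00186", "C00033", "C00469", "C00074"),
    "map00230": ("C00064", "C00037", "C00144", "C00147"),
    "map00330": ("C00148", "C00025", "C00300", "C02305", "C00062", "C00077"),
    "map00620": ("C00022", "C00186", "C00033", "C00024"),
    "map00040": ("C00137", "C00191", "C00181"),
    "map00053": ("C00137", "C00191", "C00072"),
    "map00250": ("C00041", "C00025", "C00064", "C00022", "C00049"),
    "map00260": ("C00037", "C00300", "C00065", "C00188"),
    "map00270": ("C00073", "C00022", "C00097"),
    "map00290": ("C00183", "C00123", "C00022", "C00407"),
    "map00430": ("C00245", "C00606", "C00097"),
    "map00471": ("C00064", "C00025", "C00217"),
    "map00480": ("C00025", "C00037", "C00051", "C00097"),
    "map00910": ("C00064", "C00025", "C00014"),
    "map00051": ("C00095", "C00159", "C00085"),
    "map00072": ("C00164", "C01089", "C00024"),
    "map00590": ("C00219", "C00909"),
    "map00591": ("C01595", "C00219"),
    "map00830": ("C00473", "C00376"),
    "map00980": ("C06754", "C07535"),
    "map00982": ("C07047", "C07535"),
}

_ENZYMES: dict[str, tuple[str, ...]] = {
    "map00010": ("2.7.1.40", "2.7.1.1", "1.1.1.27", "1.2.1.12"),
    "map00230": ("2.7.1.40", "2.4.2.14"),
    "map00330": ("1.5.1.2", "2.1.3.3"),
    "map00620": ("2.7.1.40", "1.1.1.27", "6.4.1.1"),
    "map00040": ("1.1.1.19",),
    "map00053": ("1.13.99.1",),
    "map00250": ("2.6.1.1",),
    "map00260": ("2.1.2.1",),
    "map00270": ("2.5.1.6",),
    "map00290": ("2.6.1.42",),
    "map00430": ("2.6.1.77",),
    "map00471": ("5.1.1.3",),
    "map00480": ("2.5.1.18",),
    "map00910": ("1.4.1.2",),
    "map00051": ("2.7.1.105", "2.7.1.1", "5.3.1.8"),
    "map00072": ("1.1.1.30", "2.3.1.9"),
    "map00590": ("1.14.99.1", "3.1.1.4"),
    "map00591": ("3.1.1.4",),
    "map00830": ("1.1.1.300", "1.1.1.105"),
    "map00980": ("1.14.14.1", "2.5.1.18"),
    "map00982": ("1.14.14.1", "1.14.13.8"),
}

# Hand-picked, mechanistically sensible reactions; other pathways get a
# generic declared-compound reaction so every file exercises the reader.
_REACTIONS: dict[str, tuple[tuple[str, str, str], ...]] = {
    "map00010": (("C00074", "C00022", "2.7.1.40"),),
    "map00620": (("C00022", "C00186", "1.1.1.27"),),
    "map00330": (("C00025", "C00148", "1.5.1.2"),),
}

#: (gene symbol, entrez id, EC number) rows of the static ID map replacing
#: the online conversion step; only enzyme-coding genes appear here.
GENE_MAP_ROWS: tuple[tuple[str, str, str], ...] = (
    ("PKM", "5315", "2.7.1.40"),
    ("HK2", "3099", "2.7.1.1"),
    ("LDHA", "3939", "1.1.1.27"),
    ("PYCR1", "5831", "1.5.1.2"),
    ("PFKFB3", "5209", "2.7.1.105"),
    ("BDH1", "622", "1.1.1.30"),
    ("PTGS2", "5743", "1.14.99.1"),
    ("PLA2G4A", "5321", "3.1.1.4"),
    ("RDH10", "157506", "1.1.1.300"),
    ("CYP1B1", "1545", "1.14.14.1"),
)

#: 56 additional up-regulated genes without an enzyme mapping (signalling,
#: transport and structural targets of the hypoxic response), padding the
#: list to the 66 entries of the mock transcriptome study.
_UNMAPPED_GENES: tuple[str, ...] = (
    "VEGFA", "CA9", "SLC2A1", "ADM", "ANGPTL4", "NDRG1", "EGLN3", "BNIP3",
    "LOX", "POSTN", "SERPINE1", "IGFBP3", "DDIT4", "P4HA1", "PLOD2", "STC1",
    "STC2", "ANKRD37", "PPP1R3C", "KDM3A", "INSIG2", "WSB1", "MXI1", "ERO1A",
    "FAM162A", "RORA", "BHLHE40", "BHLHE41", "KLF10", "ETS1", "JUN", "FOS",
    "ATF3", "EGR1", "DUSP1", "GADD45A", "CDKN1A", "CCNG2", "TP53I3", "BTG1",
    "SLC2A3", "SLC16A3", "PDK1", "EGLN1", "HIG2", "NDUFA4L2", "ANKZF1",
    "RSBN1", "TMEM45A", "KCTD11", "PGM1", "GBE1", "PYGL", "PRKCA", "ITGA5",
    "TNC",
)


def _gene_list() -> tuple[str, ...]:
    genes = tuple(sym for sym, _, _ in GENE_MAP_ROWS) + _UNMAPPED_GENES
    assert len(genes) == 66, len(genes)
    return genes


def _write_kgml(path: Path, pid: str, title: str) -> None:
    root = etree.Element(
        "pathway", name=f"path:{pid}", org="map", number=pid[3:], title=title
    )
    eid = 1
    for cid in _COMPOUNDS[pid]:
        etree.SubElement(root, "entry", id=str(eid), name=f"cpd:{cid}", type="compound")
        eid += 1
    for ec in _ENZYMES[pid]:
        etree.SubElement(root, "entry", id=str(eid), name=f"ec:{ec}", type="enzyme")
        eid += 1
    reactions = _REACTIONS.get(pid)
    if reactions is None:
        comps = _COMPOUNDS[pid]
        reactions = ((comps[0], comps[1], _ENZYMES[pid][0]),) if len(comps) >= 2 else ()
    for i, (sub, prod, ec) in enumerate(reactions, 1):
        rxn = etree.SubElement(
            root, "reaction", id=str(i), name=f"rn:R{pid[3:]}{i:02d}",
            type="reversible", enzyme=f"ec:{ec}",
        )
        etree.SubElement(rxn, "substrate", name=f"cpd:{sub}")
        etree.SubElement(rxn, "product", name=f"cpd:{prod}")
    path.write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


def make_pathway_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the pathway fixture; returns paths keyed by artifact name.

    Artifacts: ``kgml_dir`` (one XML per pathway), ``genes`` (66 IDs, one per
    line), ``gene_map`` (3-column TSV), ``panel`` (metabolite/compound TSV).
    """
    outdir = Path(outdir)
    kgml_dir = outdir / "kgml"
    try:
        kgml_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {outdir}: {exc}") from exc

    for pid, title, _, _ in PATHWAY_MEMBERSHIP:
        _write_kgml(kgml_dir / f"{pid}.xml", pid, title)

    genes_path = outdir / "genes.tsv"
    genes_path.write_text("\n".join(_gene_list()) + "\n")

    gmap_path = outdir / "gene_map.tsv"
    with open(gmap_path, "w") as fh:
        fh.write("input_id\tentrez_id\tenzyme\n")
        for sym, entrez, ec in GENE_MAP_ROWS:
            fh.write(f"{sym}\t{entrez}\tec:{ec}\n")

    panel_path = outdir / "panel.tsv"
    with open(panel_path, "w") as fh:
        fh.write("metabolite\tcompound_id\n")
        for t in default_library():
            fh.write(f"{t.name}\t{t.kegg_compound_id}\n")

    return {
        "kgml_dir": kgml_dir,
        "genes": genes_path,
        "gene_map": gmap_path,
        "panel": panel_path,
    }
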
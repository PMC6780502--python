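"""Regenerate the synthetic ``ldchip168_fixture.tsv`` panel.

The full annotation of the 168-antibody life-detector panel is not public.
This deterministic generator synthesizes a stand-in that satisfies every
documented constraint:

* 168 antibody records, of which exactly 46 are annotated Proteobacteria;
* the lettered clusters a–j (Fe–S oxidizers ... proteins and peptides) plus
  the three sole-antibody groups at peaks 35, 138 and 139;
* the handful of publicly named antibody IDs placed at their stated peaks
  (A183 at peak 3, IVF7C1 at 53, IVF8C1 at 54, IIC1C1 at 35, VIID1BF at 138,
  VD2BF at 139) and the named protein/peptide antibodies inside cluster j.

Everything else (filler IDs, immunogen text) is arbitrary but deterministic.
Run as ``python -m fsmi.data.make_ldchip168`` to rewrite the TSV in place.
"""

from __future__ import annotations

from pathlib import Path

# (cluster label, first peak, last peak, list of (phylum, count))
_CLUSTERS = [
    ("a. Fe-S oxidizers cultures", 1, 18, [("Proteobacteria", 10), ("Nitrospirae", 8)]),
    ("d. iron reducers", 19, 34, [("Proteobacteria", 10), ("Firmicutes", 6)]),
    ("geothermal environment", 35, 35, [("", 1)]),
    ("b. metal-acidic environment", 36, 50, [("Proteobacteria", 8), ("Actinobacteria", 7)]),
    ("c. psychrophilic cultures", 51, 69, [("Proteobacteria", 10), ("Bacteroidetes", 9)]),
    ("f. mesophilic cultures", 70, 84, [("Proteobacteria", 8), ("Firmicutes", 7)]),
    ("e. spores", 85, 94, [("Firmicutes", 10)]),
    ("g. archaea", 95, 109, [("Euryarchaeota", 15)]),
    ("h. cyanobacteria", 110, 118, [("Cyanobacteria", 9)]),
    ("i. perchlorate reducers", 119, 137, [("Firmicutes", 19)]),
    ("mesophilic environment", 138, 138, [("", 1)]),
    ("biofilm from mines", 139, 139, [("", 1)]),
    ("j. proteins and peptides", 140, 168, [("", 29)]),
]

# publicly named antibodies pinned to their stated peak numbers
_NAMED = {
    3: ("A183", "Leptospirillum ferroxidans"),
    35: ("IIC1C1", "geothermal environment extract"),
    53: ("IVF7C1", "Colwellia psychrerythraea"),
    54: ("IVF8C1", "Psychrobacter cryohalolentis"),
    138: ("VIID1BF", "mesophilic environment extract"),
    139: ("VD2BF", "biofilm from Mansimongs Mines Southafrica"),
}

# named protein/peptide antibodies, filled into cluster j from peak 140
_PROTEIN_IDS = [
    "NRA",
    "Prot_ApsA_RB11754",
    "Prot_DsrA_RB11365",
    "Prot_DsrB_RB11368",
    "NirS",
    "NOR1",
    "ASB",
    "ASF1",
    "Prot_FeReTs_983",
    "Prot-Pfu-FER",
]


def build_rows() -> list[list[str]]:
    rows = []
    protein_iter = iter(_PROTEIN_IDS)
    for cluster, lo, hi, phyla in _CLUSTERS:
        phylum_seq = [p for p, n in phyla for _ in range(n)]
        assert len(phylum_seq) == hi - lo + 1, cluster
        for offset, peak in enumerate(range(lo, hi + 1)):
            phylum = phylum_seq[offset]
            if peak in _NAMED:
                ab_id, source = _NAMED[peak]
            elif cluster.startswith("j."):
                try:
                    ab_id = next(protein_iter)
                    source = f"purified protein {ab_id}"
                except StopIteration:
                    ab_id = f"LD{peak:03d}"
                    source = f"synthetic peptide pool {peak}"
            else:
                ab_id = f"LD{peak:03d}"
                source = f"{phylum or 'environmental'} culture {peak}" if phylum else f"environmental extract {peak}"
            rows.append(
                [ab_id, ab_id, source, "prior_collection", cluster, phylum, "1", "synthetic"]
            )
    assert len(rows) == 168
    assert sum(1 for r in rows if r[5] == "Proteobacteria") == 46
    assert len({r[0] for r in rows}) == 168
    return rows


def main(out: Path | None = None) -> Path:
    out = out or Path(__file__).with_name("ldchip168_fixture.tsv")
    header = "antibody_id\tname\timmunogen_source\torigin\tcluster\tphylum\thas_tracer\treference\n"
    with out.open("w", encoding="utf-8") as fh:
        fh.write(header)
        for row in build_rows():
            fh.write("\t".join(row) + "\n")
    return out


if __name__ == "__main__":
    print(main())
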
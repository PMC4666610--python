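import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the dp_oracle helper module

from gbmas.panel import (BarcodeRecord, MarkerDefinition, Panel, VariantSite,
                         write_panel, write_sample_sheet)
from gbmas.dna import revcomp


def make_marker(marker_id="MK1", fwd="ACGTACGTACGTACGTA", rev="TTTTGGGGCCCCAAAAT",
                insert=None, site_offsets=(10,), mode="codominant",
                specificity="genome_specific", wild="T"):
    """Hand-built toy marker: reference = fwd + insert + revcomp(rev).

    ``site_offsets`` are 1-based offsets into the insert region.
    """
    if insert is None:
        insert = ("ACCAGTTGACCTGGATCCAAGGTTCCAAGGTTGCATGCAT"
                  "CCGGAATTCCGGTTAACCGGTTAACCGGATAT"[:60])
        insert = insert + "GATTACAGATTACA"[:max(0, 80 - len(fwd) - len(rev) - len(insert))]
    amplicon = fwd + insert + revcomp(rev)
    assert len(amplicon) >= 80, "toy amplicon must satisfy the 80 nt floor"
    sites = []
    for off in site_offsets:
        pos = len(fwd) + off
        fav = amplicon[pos - 1]
        wt = "A" if fav != "A" else "G"
        sites.append(VariantSite(site_id=f"SNP{pos}", position=pos,
                                 favorable_base=fav, wild_type_base=wt))
    return MarkerDefinition(marker_id=marker_id, forward_primer=fwd,
                            reverse_primer=rev, reference_amplicon=amplicon,
                            sites=tuple(sites), mode=mode, specificity=specificity)


@pytest.fixture
def toy_marker():
    return make_marker()


@pytest.fixture
def toy_panel():
    m1 = make_marker("MK1", fwd="ACGTACGTACGTACGTA", rev="TTTTGGGGCCCCAAAAT")
    m2 = make_marker("MK2", fwd="GGCCAATTGGCCAATTG", rev="CATCATCATGGTGGTGG",
                     specificity="semi_specific")
    samples = [
        BarcodeRecord("S01", "ACACACACAC", is_positive_control_for=("MK1", "MK2")),
        BarcodeRecord("S02", "GTGTGTGTGT"),
    ]
    return Panel(markers=[m1, m2], samples=samples)


@pytest.fixture
def panel_files(tmp_path, toy_panel):
    tsv, fasta, sheet = tmp_path / "panel.tsv", tmp_path / "panel.fasta", tmp_path / "samples.tsv"
    write_panel(toy_panel, tsv, fasta)
    write_sample_sheet(toy_panel.samples, sheet)
    return tsv, fasta, sheet
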
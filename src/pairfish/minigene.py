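"""A compact ErbB4-like multi-isoform gene model for demos and tests.

ErbB4 alternative splicing produces four receptor isoforms from two choices:
the mutually exclusive juxtamembrane exons JMa (75 bp, metalloprotease
cleavable) vs JMb (45 bp), and inclusion (CYT-1) vs exclusion (CYT-2) of a
48 bp cytoplasmic exon.  The exon fragments flanking each splice junction in
this model are the published sense-strand target regions of the ten
junction-specific single-pair probes for this gene; the interior of each exon
is deterministic SYNTHETIC filler (this is a synthetic stand-in for the full
transcript sequences, which are not needed to exercise junction-probe
design).  Exon sizes honour the real gene where known (JMa 75 nt, JMb 45 nt,
CYT-1 cassette 48 nt); runs of constitutive exons are collapsed into single
placeholder blocks (``E4_14``, ``E18_24``).
"""

from __future__ import annotations

from .probes import TranscriptIsoform

# exon sequences; junction-flanking segments are the published probe targets,
# interior filler is synthetic
_EXONS: dict[str, str] = {
    "E1": "ATGGCTCTGAGACCGTCAAGTGGA" "TCTCAGTCAG",
    "E2": (
        "TGTGCGCAGGAACAGAGAACAAACTGAGCTCTCTCT"
        "ACCTGATTCGAGTCCAAGGTTCAA"
        "GAGCACAACCGGGACCTCTCCTTCCTGCGG"
    ),
    "E3": "TCTATCCGAG" "GATTACCTGTCAGGCATCGTAGCA",
    "E4_14": "CAGTTAGCAGATACCGGTTCTGAACGTCATGGATCCTACG",
    "E15": "GCTGACCATTGACGTATCCG" "CCCAGGG",
    # JMb, 45 nt
    "E16a": "GTGCATAGGTTCAAGCATTGAAGACTGCATCGGCCTGACGGATAG",
    # JMa, 75 nt
    "E16b": (
        "GTGTAACGGTCCCACTAGTCATGACTGCATTTACTACCC"
        "CA"
        "GGACGGGCCATTCCACTTTACCACAACACGCTAG"
    ),
    "E17": "AACTCCAC" "TGGTCAAGGTCTAGCATCCA",
    "E18_24": "TACGGATCCATGACGTTCAGAACCGGTATCTGCTAACTGC",
    "E25": "AGTCCTGGTTACGAGCAAGC" "CCATCTACACATCCAGAACAAGAATTGACTCCAATAGG",
    # CYT-1 cassette, 48 nt
    "E26": "AGTGAAATTGGAC" "TGCTAGACCTGGAACTGTCAGATC" "CCATGTCGGGA",
    "E27": (
        "AATCAGTTTGTGTACCAAGATGGGGGCTTT"
        "GTACCAGTTGACGGTCTTGA"
        "GCATGACAAGCCCAAACAAG"
    ),
    "E28": "AATATCTGAATCCTGTGGAAGAGAACC" "GTCAGGATCTACCGTTGCAA",
}

_COMMON_5P = ["E1", "E2", "E3", "E4_14", "E15"]
_COMMON_MID = ["E17", "E18_24", "E25"]
_COMMON_3P = ["E27", "E28"]


def _isoform(isoform_id: str, jm_exon: str, cyt1: bool) -> TranscriptIsoform:
    order = (
        _COMMON_5P + [jm_exon] + _COMMON_MID
        + (["E26"] if cyt1 else []) + _COMMON_3P
    )
    return TranscriptIsoform(isoform_id, [(e, _EXONS[e]) for e in order])


def erbb4_minigene() -> list[TranscriptIsoform]:
    """The four-isoform model: JMa/CYT-1, JMa/CYT-2, JMb/CYT-1, JMb/CYT-2."""
    return [
        _isoform("JMa_CYT1", "E16b", cyt1=True),
        _isoform("JMa_CYT2", "E16b", cyt1=False),
        _isoform("JMb_CYT1", "E16a", cyt1=True),
        _isoform("JMb_CYT2", "E16a", cyt1=False),
    ]


#: the ten published junction probes: (probe name, junction, isoform to
#: design against)
PUBLISHED_PROBES: list[tuple[str, tuple[str, str], str]] = [
    ("JMa 15/16b", ("E15", "E16b"), "JMa_CYT2"),
    ("JMa 16b/17", ("E16b", "E17"), "JMa_CYT2"),
    ("JMb 15/16a", ("E15", "E16a"), "JMb_CYT2"),
    ("JMb 16a/17", ("E16a", "E17"), "JMb_CYT2"),
    ("CYT-1 25/26", ("E25", "E26"), "JMb_CYT1"),
    ("CYT-1 26/27", ("E26", "E27"), "JMb_CYT1"),
    ("CYT-2 25/27", ("E25", "E27"), "JMb_CYT2"),
    ("pan 1/2", ("E1", "E2"), "JMb_CYT2"),
    ("pan 2/3", ("E2", "E3"), "JMb_CYT2"),
    ("pan 27/28", ("E27", "E28"), "JMb_CYT2"),
]
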
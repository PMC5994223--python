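"""Design and screening of exon-junction single-pair ISH probes.

A "single-pair probe" is one pair of 18-25 nt anti-sense oligonucleotides in
which one oligo hybridizes across an exon-exon junction of a spliced mRNA and
the other hybridizes to the immediately adjacent sequence.  Because signal
amplification requires joint hybridization of both oligos of the pair, a probe
whose spanning oligo covers a junction unique to one splice isoform detects
that isoform only.  This module designs such pairs against a multi-isoform
gene model, screens the junction-spanning oligo for exact-sequence occurrence
in the other isoforms, and reads/writes the associated plain-text formats.

Coordinates are 0-based half-open in transcript space.  Probe records store
the *sense-strand* target sequence (the convention used when publishing probe
targets); the synthesized oligos are the reverse complements (anti-sense).
The junction in a target sequence is marked with ``/`` (``-`` accepted on
input).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio.Seq import Seq

log = logging.getLogger(__name__)

JUNCTION_MARKER = "/"
_ACCEPTED_MARKERS = ("/", "-")
_VALID_BASES = frozenset("ACGT")

DEFAULT_OLIGO_LEN_RANGE = (18, 25)
DEFAULT_MIN_OVERHANG = 4
DEFAULT_GC_RANGE = (0.30, 0.70)

Side = Literal["adjacent-upstream", "adjacent-downstream"]


class ProbeDesignError(ValueError):
    """Invalid gene model or probe geometry."""


@dataclass(frozen=True)
class TranscriptIsoform:
    """One splice isoform: an ordered list of (exon_id, sequence) blocks."""

    isoform_id: str
    exons: tuple[tuple[str, str], ...]

    def __init__(self, isoform_id: str, exons: Iterable[tuple[str, str]]):
        norm = []
        seen = set()
        for exon_id, seq in exons:
            seq = seq.upper()
            if not seq:
                raise ProbeDesignError(
                    f"{isoform_id}/{exon_id}: empty exon sequence"
                )
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ProbeDesignError(
                    f"{isoform_id}/{exon_id}: non-ACGT characters {sorted(bad)}"
                )
            if exon_id in seen:
                raise ProbeDesignError(
                    f"{isoform_id}: duplicate exon id {exon_id!r}"
                )
            seen.add(exon_id)
            norm.append((exon_id, seq))
        if not norm:
            raise ProbeDesignError(f"{isoform_id}: isoform has no exons")
        object.__setattr__(self, "isoform_id", isoform_id)
        object.__setattr__(self, "exons", tuple(norm))

    @property
    def sequence(self) -> str:
        """Full transcript sequence (concatenation of exons in order)."""
        return "".join(seq for _, seq in self.exons)

    def __len__(self) -> int:
        return sum(len(seq) for _, seq in self.exons)

    def exon_offsets(self) -> list[int]:
        """Transcript-coordinate start offset of each exon."""
        offsets, pos = [], 0
        for _, seq in self.exons:
            offsets.append(pos)
            pos += len(seq)
        return offsets

    def reverse_complement(self) -> "TranscriptIsoform":
        """Model of the reverse-complement transcript (exon order reversed)."""
        rc = [
            (exon_id, str(Seq(seq).reverse_complement()))
            for exon_id, seq in reversed(self.exons)
        ]
        return TranscriptIsoform(self.isoform_id, rc)


@dataclass(frozen=True)
class ExonJunction:
    isoform_id: str
    upstream_exon_id: str
    downstream_exon_id: str
    junction_pos: int  # transcript coordinate of first base of downstream exon

    @property
    def label(self) -> str:
        return f"{self.upstream_exon_id}/{self.downstream_exon_id}"


@dataclass(frozen=True)
class SinglePairProbe:
    """A designed pair: junction-spanning oligo + immediately adjacent oligo.

    ``target_sequence`` is the sense-strand transcript substring covered by
    both oligos, with :data:`JUNCTION_MARKER` inserted at the junction.  The
    physical probes are the anti-sense reverse complements
    (``antisense=True`` records this convention).
    """

    name: str
    junction: ExonJunction
    target_sequence: str
    oligo_span: tuple[int, int]
    oligo_adjacent: tuple[int, int]
    side: Side
    antisense: bool = True

    @property
    def covered_interval(self) -> tuple[int, int]:
        lo = min(self.oligo_span[0], self.oligo_adjacent[0])
        hi = max(self.oligo_span[1], self.oligo_adjacent[1])
        return lo, hi

    def oligo_sequences(self, isoform: TranscriptIsoform) -> tuple[str, str]:
        """(spanning, adjacent) sense-strand oligo sequences."""
        t = isoform.sequence
        return (
            t[self.oligo_span[0] : self.oligo_span[1]],
            t[self.oligo_adjacent[0] : self.oligo_adjacent[1]],
        )


@dataclass
class SpecificityReport:
    probe_name: str
    off_target_isoforms: list[str] = field(default_factory=list)
    specific: bool = True


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def enumerate_junctions(isoform: TranscriptIsoform) -> list[ExonJunction]:
    """All exon-exon junctions of an isoform, in transcript order.

    A single-exon isoform has no junctions and yields ``[]``.
    """
    junctions = []
    pos = 0
    exons = isoform.exons
    for (up_id, up_seq), (down_id, _) in zip(exons, exons[1:]):
        pos += len(up_seq)
        junctions.append(
            ExonJunction(isoform.isoform_id, up_id, down_id, pos)
        )
    return junctions


def _junction_of(isoform: TranscriptIsoform, upstream: str, downstream: str) -> ExonJunction:
    for j in enumerate_junctions(isoform):
        if (j.upstream_exon_id, j.downstream_exon_id) == (upstream, downstream):
            return j
    raise ProbeDesignError(
        f"{isoform.isoform_id} has no junction {upstream}/{downstream}"
    )


def design_probes(
    isoform: TranscriptIsoform,
    junction: ExonJunction,
    *,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    oligo_len_range: tuple[int, int] = DEFAULT_OLIGO_LEN_RANGE,
    gc_range: tuple[float, float] = DEFAULT_GC_RANGE,
) -> list[SinglePairProbe]:
    """Enumerate all valid single-pair probes for one junction.

    The junction-spanning oligo must extend at least ``min_overhang`` bases
    into each exon; the partner oligo abuts it with zero gap, on either side
    (both placements are produced when the transcript permits).  Each oligo
    must satisfy the length and GC constraints.  Output is deterministic,
    ordered by spanning-oligo start, then length, then side, then partner
    length.
    """
    if junction.isoform_id != isoform.isoform_id:
        raise ProbeDesignError(
            f"junction {junction.label} belongs to {junction.isoform_id}, "
            f"not {isoform.isoform_id}"
        )
    _junction_of(isoform, junction.upstream_exon_id, junction.downstream_exon_id)

    t = isoform.sequence
    n = len(t)
    j = junction.junction_pos
    lo_len, hi_len = oligo_len_range
    gc_lo, gc_hi = gc_range

    def gc_ok(s: int, e: int) -> bool:
        return gc_lo <= gc_fraction(t[s:e]) <= gc_hi

    probes: list[SinglePairProbe] = []
    for span_len in range(lo_len, hi_len + 1):
        # spanning oligo [s, s+span_len) with >= min_overhang on each side
        s_min = max(0, j + min_overhang - span_len)
        s_max = min(j - min_overhang, n - span_len)
        for s in range(s_min, s_max + 1):
            e = s + span_len
            if not gc_ok(s, e):
                continue
            for adj_len in range(lo_len, hi_len + 1):
                # adjacent-upstream: [s - adj_len, s)
                if s - adj_len >= 0 and gc_ok(s - adj_len, s):
                    probes.append(
                        _make_probe(isoform, junction, (s, e),
                                    (s - adj_len, s), "adjacent-upstream")
                    )
                # adjacent-downstream: [e, e + adj_len)
                if e + adj_len <= n and gc_ok(e, e + adj_len):
                    probes.append(
                        _make_probe(isoform, junction, (s, e),
                                    (e, e + adj_len), "adjacent-downstream")
                    )
    probes.sort(
        key=lambda p: (
            p.oligo_span[0],
            p.oligo_span[1] - p.oligo_span[0],
            p.side,
            p.oligo_adjacent[1] - p.oligo_adjacent[0],
        )
    )
    if not probes:
        log.warning(
            "no valid probe placement for junction %s of %s "
            "(junction too close to a transcript end, or GC bounds)",
            junction.label, isoform.isoform_id,
        )
    return probes


def _make_probe(
    isoform: TranscriptIsoform,
    junction: ExonJunction,
    span: tuple[int, int],
    adjacent: tuple[int, int],
    side: Side,
) -> SinglePairProbe:
    t = isoform.sequence
    lo = min(span[0], adjacent[0])
    hi = max(span[1], adjacent[1])
    j = junction.junction_pos
    target = t[lo:j] + JUNCTION_MARKER + t[j:hi]
    name = (
        f"{isoform.isoform_id}|{junction.upstream_exon_id}-"
        f"{junction.downstream_exon_id}|{span[0]}-{span[1]}|"
        f"{'up' if side == 'adjacent-upstream' else 'down'}"
    )
    return SinglePairProbe(
        name=name,
        junction=junction,
        target_sequence=target,
        oligo_span=span,
        oligo_adjacent=adjacent,
        side=side,
    )


def isoform_has_junction(isoform: TranscriptIsoform, junction: ExonJunction) -> bool:
    """True if the isoform contains the same consecutive exon pair."""
    return any(
        (j.upstream_exon_id, j.downstream_exon_id)
        == (junction.upstream_exon_id, junction.downstream_exon_id)
        for j in enumerate_junctions(isoform)
    )


def check_specificity(
    probe: SinglePairProbe,
    gene_model: Sequence[TranscriptIsoform],
    *,
    designed_against: TranscriptIsoform | None = None,
) -> SpecificityReport:
    """Screen the junction-spanning oligo against every isoform's transcript.

    The oligo sequence is searched as an exact substring (no thermodynamic
    mismatch model).  The probe is *specific* iff every isoform in which the
    oligo occurs actually carries the targeted junction — i.e. the probe
    cannot light up an isoform that lacks it.
    """
    if designed_against is None:
        designed_against = next(
            (iso for iso in gene_model
             if iso.isoform_id == probe.junction.isoform_id),
            None,
        )
        if designed_against is None:
            raise ProbeDesignError(
                f"gene model does not contain isoform "
                f"{probe.junction.isoform_id} the probe was designed against"
            )
    span_seq = designed_against.sequence[
        probe.oligo_span[0] : probe.oligo_span[1]
    ]
    hits = [iso.isoform_id for iso in gene_model if span_seq in iso.sequence]
    specific = all(
        isoform_has_junction(iso, probe.junction)
        for iso in gene_model
        if iso.isoform_id in hits
    )
    return SpecificityReport(
        probe_name=probe.name, off_target_isoforms=hits, specific=specific
    )


# ---------------------------------------------------------------------------
# gene-model and probe I/O

def load_gene_model(path: str | Path) -> list[TranscriptIsoform]:
    """Read a gene model from TSV (isoform_id, exon_id, sequence) or FASTA
    with ``isoform|exon`` headers; exon order is file order."""
    path = Path(path)
    text = path.read_text()
    records: dict[str, list[tuple[str, str]]] = {}
    if text.lstrip().startswith(">"):
        header, chunks = None, []
        entries = []
        for line in text.splitlines():
            if line.startswith(">"):
                if header is not None:
                    entries.append((header, "".join(chunks)))
                header, chunks = line[1:].strip(), []
            elif line.strip():
                chunks.append(line.strip())
        if header is not None:
            entries.append((header, "".join(chunks)))
        for header, seq in entries:
            if "|" not in header:
                raise ProbeDesignError(
                    f"FASTA header {header!r} is not 'isoform|exon'"
                )
            isoform_id, exon_id = header.split("|", 1)
            records.setdefault(isoform_id, []).append((exon_id, seq))
    else:
        reader = csv.reader(
            (l for l in text.splitlines() if l.strip() and not l.startswith("#")),
            delimiter="\t",
        )
        rows = list(reader)
        if rows and rows[0][:2] == ["isoform_id", "exon_id"]:
            rows = rows[1:]
        for row in rows:
            if len(row) < 3:
                raise ProbeDesignError(f"malformed gene-model row: {row!r}")
            records.setdefault(row[0], []).append((row[1], row[2]))
    return [TranscriptIsoform(iso, exons) for iso, exons in records.items()]


_TSV_COLUMNS = [
    "name", "isoform_id", "junction", "junction_pos", "span_start", "span_end",
    "adjacent_start", "adjacent_end", "side", "specific", "target_sequence",
]


def export_probes(
    probes: Sequence[SinglePairProbe],
    path: str | Path,
    fmt: str = "tsv",
    *,
    isoforms: Sequence[TranscriptIsoform] | None = None,
    reports: Sequence[SpecificityReport] | None = None,
) -> Path:
    """Write probes as TSV (Table-style), FASTA (one record per oligo, needs
    ``isoforms``) or BED (transcript-space intervals)."""
    if not probes:
        raise ProbeDesignError("refusing to export an empty probe list")
    path = Path(path)
    by_name = {r.probe_name: r for r in reports or []}
    if fmt == "tsv":
        with path.open("w", newline="") as fh:
            fh.write(
                "# target sequences are sense strand; synthesized oligos are "
                "anti-sense; junction marked '/'\n"
            )
            w = csv.writer(fh, delimiter="\t")
            w.writerow(_TSV_COLUMNS)
            for p in probes:
                rep = by_name.get(p.name)
                w.writerow([
                    p.name, p.junction.isoform_id, p.junction.label,
                    p.junction.junction_pos, p.oligo_span[0], p.oligo_span[1],
                    p.oligo_adjacent[0], p.oligo_adjacent[1], p.side,
                    "" if rep is None else str(rep.specific).lower(),
                    p.target_sequence,
                ])
    elif fmt == "fasta":
        if isoforms is None:
            raise ProbeDesignError("FASTA export needs the isoform sequences")
        iso_by_id = {iso.isoform_id: iso for iso in isoforms}
        with path.open("w") as fh:
            for p in probes:
                iso = iso_by_id[p.junction.isoform_id]
                span_seq, adj_seq = p.oligo_sequences(iso)
                fh.write(f">{p.name}|span sense-strand target\n{span_seq}\n")
                fh.write(f">{p.name}|adjacent sense-strand target\n{adj_seq}\n")
    elif fmt == "bed":
        with path.open("w") as fh:
            for p in probes:
                chrom = p.junction.isoform_id
                fh.write(
                    f"{chrom}\t{p.oligo_span[0]}\t{p.oligo_span[1]}\t{p.name}|span\n"
                )
                fh.write(
                    f"{chrom}\t{p.oligo_adjacent[0]}\t{p.oligo_adjacent[1]}\t"
                    f"{p.name}|adjacent\n"
                )
    else:
        raise ProbeDesignError(f"unknown export format {fmt!r}")
    return path


def parse_probe_table(path: str | Path) -> list[SinglePairProbe]:
    """Re-read a TSV written by :func:`export_probes` (round-trip safe)."""
    probes = []
    with Path(path).open() as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    header = rows[0]
    for row in rows[1:]:
        rec = dict(zip(header, row))
        target = rec["target_sequence"]
        for marker in _ACCEPTED_MARKERS[1:]:
            target = target.replace(marker, JUNCTION_MARKER)
        up, down = rec["junction"].split("/", 1)
        probes.append(
            SinglePairProbe(
                name=rec["name"],
                junction=ExonJunction(
                    rec["isoform_id"], up, down, int(rec["junction_pos"])
                ),
                target_sequence=target,
                oligo_span=(int(rec["span_start"]), int(rec["span_end"])),
                oligo_adjacent=(
                    int(rec["adjacent_start"]), int(rec["adjacent_end"])
                ),
                side=rec["side"],  # type: ignore[arg-type]
            )
        )
    return probes
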
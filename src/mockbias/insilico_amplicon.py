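"""Degenerate-primer in-silico PCR over 16S rRNA gene sequences, plus
genome GC and 16S-feature counting.

Conventions
-----------
* All coordinates are 0-based, half-open.
* Amplicon lengths are PRIMER-EXCLUDED: ``trimmed_length`` spans the insert
  between the two primer footprints. (With the V3 pair the forward and
  reverse footprints are 21 + 20 = 41 nt, so a 201 nt primer-inclusive
  product reports 160.)
* GC counts G, C and the degenerate symbol S; other ambiguity codes are
  excluded from numerator and denominator.
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "PrimerPair",
    "AmpliconResult",
    "FeatureRecord",
    "AmpliconNotFoundError",
    "IUPAC_SETS",
    "iupac_mismatches",
    "reverse_complement",
    "find_amplicon",
    "modal_amplicon_length",
    "gc_percent",
    "genome_gc",
    "count_16s_features",
    "read_fasta",
    "write_fasta",
    "read_gff_features",
    "read_genbank_features",
    "extract_feature_sequences",
    "load_primer_table",
    "region_primer_pairs",
    "REGIONS",
]

REGIONS = ("V1-V2", "V3", "V4", "V1-V3", "V1-V9")

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class AmpliconNotFoundError(ValueError):
    """No qualifying primer site on the template."""


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair targeting one variable region.

    ``forward`` and ``reverse`` are both written 5'->3' as synthesized; the
    reverse primer is matched against the template as its reverse complement.
    """

    region: str
    forward: str
    reverse: str
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not seq:
                raise ValueError("empty primer sequence")
            bad = set(seq.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"non-IUPAC symbols in primer: {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class AmpliconResult:
    """Primer-trimmed in-silico PCR product on one template."""

    strain: str
    region: str
    insert_start: int
    insert_end: int
    gc_percent: float

    @property
    def trimmed_length(self) -> int:
        return self.insert_end - self.insert_start


@dataclass(frozen=True)
class FeatureRecord:
    """Minimal annotation feature: type, location, product/name."""

    seqid: str
    type: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    product: str


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide symbol {exc.args[0]!r}") from None


def iupac_mismatches(pattern: str, window: str) -> int:
    """Count positions of ``window`` not covered by ``pattern``'s IUPAC sets.

    ``pattern`` may be degenerate; ``window`` must be plain A/C/G/T.
    """
    if len(pattern) != len(window):
        raise ValueError(f"length mismatch: {len(pattern)} vs {len(window)}")
    n = 0
    for p, w in zip(pattern.upper(), window.upper()):
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {p!r} in pattern") from None
        if w not in "ACGT":
            raise ValueError(f"invalid template base {w!r}")
        if w not in allowed:
            n += 1
    return n


def _best_site(template: str, pattern: str, start: int = 0) -> tuple[int, int] | None:
    """Leftmost window with the minimum mismatch count; returns (pos, mm)."""
    k = len(pattern)
    best: tuple[int, int] | None = None
    ties = []
    for i in range(start, len(template) - k + 1):
        mm = iupac_mismatches(pattern, template[i : i + k])
        if best is None or mm < best[1]:
            best = (i, mm)
            ties = [i]
        elif mm == best[1]:
            ties.append(i)
    if best is not None and len(ties) > 1:
        log.warning(
            "primer %s...: %d equally good sites at %s; keeping leftmost",
            pattern[:8], len(ties), ties[:5],
        )
    return best


def find_amplicon(
    template: str,
    pair: PrimerPair,
    *,
    strain: str = "",
) -> AmpliconResult:
    """Locate the primer pair on a template and return the trimmed insert.

    The forward site is the leftmost window minimizing mismatches (required
    <= ``max_mismatches``); the reverse site is the leftmost window downstream
    of the forward footprint matching the reverse complement of the reverse
    primer within ``max_mismatches``.
    """
    template = template.upper()
    if len(template) <= len(pair.forward) + len(pair.reverse):
        raise ValueError("template shorter than the combined primer lengths")
    fwd = _best_site(template, pair.forward.upper())
    if fwd is None or fwd[1] > pair.max_mismatches:
        raise AmpliconNotFoundError(
            f"{strain or 'template'}: no forward site for {pair.region} "
            f"within {pair.max_mismatches} mismatches"
        )
    insert_start = fwd[0] + len(pair.forward)
    rc = reverse_complement(pair.reverse)
    k = len(rc)
    insert_end = None
    for i in range(insert_start, len(template) - k + 1):
        if iupac_mismatches(rc, template[i : i + k]) <= pair.max_mismatches:
            insert_end = i
            break
    if insert_end is None:
        raise AmpliconNotFoundError(
            f"{strain or 'template'}: no reverse site downstream for {pair.region} "
            f"within {pair.max_mismatches} mismatches"
        )
    if insert_end <= insert_start:
        raise AmpliconNotFoundError(
            f"{strain or 'template'}: primer footprints overlap for {pair.region}"
        )
    insert = template[insert_start:insert_end]
    return AmpliconResult(
        strain=strain,
        region=pair.region,
        insert_start=insert_start,
        insert_end=insert_end,
        gc_percent=gc_percent(insert),
    )


def modal_amplicon_length(templates: Sequence[str], pair: PrimerPair, *, strain: str = "") -> int:
    """Run :func:`find_amplicon` over every 16S copy and return the modal
    trimmed length (ties broken toward the smaller length)."""
    lengths = []
    for t in templates:
        try:
            lengths.append(find_amplicon(t, pair, strain=strain).trimmed_length)
        except AmpliconNotFoundError:
            continue
    if not lengths:
        raise AmpliconNotFoundError(f"{strain or 'templates'}: no copy yielded an amplicon")
    return statistics.mode(sorted(lengths))


def gc_percent(sequence: str) -> float:
    """GC percent over unambiguous positions (G, C, A, T and S; S counts GC)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GCS")
    counted = gc + seq.count("A") + seq.count("T")
    if counted == 0:
        raise ValueError("sequence has no unambiguous bases")
    return 100.0 * gc / counted


def genome_gc(fasta_path: str | Path) -> float:
    """Genome-wide GC percent pooled over all contigs of a FASTA file."""
    gc = at = 0
    for _, seq in read_fasta(fasta_path):
        s = seq.upper()
        gc += sum(s.count(b) for b in "GCS")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError(f"no unambiguous bases in {fasta_path}")
    return 100.0 * gc / (gc + at)


def count_16s_features(features: Iterable[FeatureRecord]) -> int:
    """Number of rRNA-type features whose product/name mentions 16S."""
    n = 0
    for f in features:
        if f.type.lower() == "rrna" and "16s" in f.product.lower():
            n += 1
    return n


# --- sequence / annotation I/O ----------------------------------------------


def read_fasta(source: str | Path | TextIO) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA as ``[(id, sequence), ...]``."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(source, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], dest: str | Path, *, width: int = 70) -> None:
    with open(dest, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip().lower() == key:
                return v.strip()
    return None


def read_gff_features(source: str | Path) -> list[FeatureRecord]:
    """Parse GFF3 into minimal feature records (type/coordinates/product)."""
    out = []
    with open(source, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line[:80]!r}")
            product = _gff_attr(cols[8], "product") or _gff_attr(cols[8], "name") or ""
            out.append(
                FeatureRecord(
                    seqid=cols[0],
                    type=cols[2],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    product=product,
                )
            )
    return out


def read_genbank_features(source: str | Path) -> list[FeatureRecord]:
    """Parse a GenBank flat file into minimal feature records."""
    out = []
    for rec in SeqIO.parse(str(source), "genbank"):
        for feat in rec.features:
            product = ""
            for key in ("product", "gene", "note"):
                if key in feat.qualifiers:
                    product = feat.qualifiers[key][0]
                    break
            out.append(
                FeatureRecord(
                    seqid=rec.id,
                    type=feat.type,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    product=product,
                )
            )
    return out


def extract_feature_sequences(
    fasta_path: str | Path, features: Iterable[FeatureRecord]
) -> list[str]:
    """Extract strand-corrected sequences of features from a genome FASTA."""
    contigs = dict(read_fasta(fasta_path))
    seqs = []
    for f in features:
        if f.seqid not in contigs:
            raise KeyError(f"feature contig {f.seqid!r} absent from FASTA")
        s = contigs[f.seqid][f.start : f.end]
        seqs.append(reverse_complement(s) if f.strand == "-" else s)
    return seqs


# --- packaged primer table ---------------------------------------------------

# Region -> (forward, reverse) primer names in the packaged table. The
# bif27F variant replaces 27F for Bifidobacterium templates.
_REGION_PRIMER_NAMES = {
    "V1-V2": ("27F", "337R"),
    "V3": ("337F", "518R"),
    "V4": ("518F", "800R"),
    "V1-V3": ("27F", "518R"),
    "V1-V9": ("27F", "1492R"),
}

_CORE_PRIMERS = {
    "27F": "AGAGTTTGATCMTGGCTCAG",
    "bif27F": "GGGTTCGATTCTGGCTCAG",
    "337R": "CTGCWGCCTCCCGTAGGAGTC",
    "337F": "GACTCCTACGGGAGGCWGCAG",
    "518R": "CGTATTACCGCGGCTGCTGG",
    "518F": "CCAGCAGCCGCGGTAATACG",
    "800R": "TACCAGGGTATCTAATCC",
    "1492R": "TACGGYTACCTTGTTACGACTT",
}


def load_primer_table() -> list[dict[str, str]]:
    """The full published primer table (platform, name, sequence, purpose)."""
    text = resources.files("mockbias.data").joinpath("primers.tsv").read_text(encoding="utf-8")
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


def region_primer_pairs(
    *, bifido: bool = False, max_mismatches: int = 1
) -> dict[str, PrimerPair]:
    """Primer pairs per variable region.

    With ``bifido=True`` the Bifidobacterium-specific bif27F replaces 27F
    wherever it is the forward primer.
    """
    pairs = {}
    for region, (fname, rname) in _REGION_PRIMER_NAMES.items():
        if bifido and fname == "27F":
            fname = "bif27F"
        pairs[region] = PrimerPair(
            region=region,
            forward=_CORE_PRIMERS[fname],
            reverse=_CORE_PRIMERS[rname],
            max_mismatches=max_mismatches,
        )
    return pairs
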
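"""In-silico evaluation of FISH probes and PCR primers.

Ungapped sliding-window mismatch counting of an oligonucleotide against
rRNA gene sequences, with IUPAC-degeneracy awareness, N exclusion and
strand handling.  This mirrors desk-scale probe checking: a probe (or a
reverse primer) hybridises to the sense strand, so its reverse complement
is slid along the gene-sense target; a forward primer is matched
directly.  Windows overlapping an N in the target are skipped, and — as
in database probe-coverage checks — sequences containing N bases are
excluded from coverage statistics altogether.

The probes and primers established for this symbiosis (the *Ca.* Azoamicus
probe eub62A3_813, the plagiopylid 18S probe plagi_1083, the primer pair
plagi_289_F / plagi_1107_R, and the general eukaryote probe set with the
KIN 516 competitor) ship as ready-made :class:`Oligo` objects in
:data:`FIELD_OLIGOS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import SeqIO

from .errors import FormatError, UndefinedResultError, ValidationError

#: IUPAC nucleotide codes -> set of matching concrete bases
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "U": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (RNA U -> DNA)."""
    seq = sequence.upper()
    bad = set(seq) - set(_COMPLEMENT)
    if bad:
        raise FormatError(f"non-IUPAC character(s) {sorted(bad)} in sequence")
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class Oligo:
    """A probe or primer, sequence written 5'→3'."""

    name: str
    sequence: str
    kind: str = "probe"  # "probe" or "primer"
    target_molecule: str = ""  # "16S" or "18S"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValidationError("oligo sequence must be non-empty")
        bad = set(self.sequence) - set(IUPAC_SETS)
        if bad:
            raise FormatError(
                f"oligo {self.name}: non-IUPAC character(s) {sorted(bad)}"
            )
        if self.kind not in ("probe", "primer"):
            raise ValidationError(f"oligo kind must be probe/primer, got {self.kind!r}")

    def oriented(self, orientation: str = "auto") -> str:
        """Sequence as it appears on the gene-sense strand.

        Probes and reverse primers hybridise to the sense strand, so they
        appear on it as their reverse complement; forward primers (name
        ending in ``f``) match directly.
        """
        if orientation == "auto":
            is_forward = self.kind == "primer" and self.name.lower().rstrip(
                "0123456789_"
            ).endswith("f")
            orientation = "sense" if is_forward else "antisense"
        if orientation == "sense":
            return self.sequence
        if orientation == "antisense":
            return reverse_complement(self.sequence)
        raise ValidationError(f"unknown orientation {orientation!r}")


@dataclass
class MatchReport:
    """Best ungapped match of one oligo in one target sequence."""

    oligo_name: str
    sequence_id: str
    best_mismatches: Optional[int]  # None if no window within the allowance
    position: Optional[int]  # 0-based offset of the best window
    excluded_for_N: bool  # at least one window was skipped over an N


#: probe and primer sequences established for this symbiosis
FIELD_OLIGOS: dict[str, Oligo] = {
    o.name: o
    for o in [
        Oligo("eub62A3_813", "CTAACAGCAAGTTTTCATCGTTTA", "probe", "16S"),
        Oligo("plagi_1083", "TTGTGTCCATACTTCCCCC", "probe", "18S"),
        Oligo("plagi_289_F", "TCAAGTTTCTGCCCTATCAC", "primer", "18S"),
        Oligo("plagi_1107_R", "TCAGACTTGTGTCCATACTT", "primer", "18S"),
        Oligo("EUK_1209", "GGGCATCACAGACCTG", "probe", "18S"),
        Oligo("EUK_502", "ACCAGACTTGCCCTCC", "probe", "18S"),
        Oligo("EUK_309", "TCAGGCTCCCTCTCCGG", "probe", "18S"),
        Oligo("EUK_B", "TGATCCTTCTGCAGGTTCACCTAC", "probe", "18S"),
        Oligo("KIN_516", "ACCAGACTTGTCCTCC", "probe", "18S"),
        Oligo("Non388", "ACTCCTACGGGAGGCAGC", "probe", "16S"),
    ]
}


def _target_id_seq(target) -> tuple[str, str]:
    if isinstance(target, str):
        return "target", target.upper().replace("U", "T")
    if isinstance(target, tuple):
        return target[0], target[1].upper().replace("U", "T")
    # Bio.SeqRecord
    return target.id, str(target.seq).upper().replace("U", "T")


def match_oligo(
    oligo: Oligo,
    target,
    max_mismatches: int = 0,
    orientation: str = "auto",
    both_strands: bool = False,
) -> MatchReport:
    """Slide ``oligo`` along a gene-sense target and report the minimum
    mismatch window.

    A position mismatches when the target base is not within the IUPAC
    set of the (strand-oriented) oligo base.  Windows overlapping an N in
    the target are skipped and flag ``excluded_for_N``.  ``target`` may
    be a string, an ``(id, sequence)`` pair, or a ``SeqRecord``.
    ``both_strands=True`` additionally matches the opposite orientation
    and keeps the better hit.
    """
    if max_mismatches < 0:
        raise ValidationError("max_mismatches >= 0 required")
    seq_id, t = _target_id_seq(target)
    bad = set(t) - set("ACGTN")
    if bad:
        raise FormatError(
            f"target {seq_id}: non-nucleotide character(s) {sorted(bad)}"
        )
    queries = [oligo.oriented(orientation)]
    if both_strands:
        queries.append(reverse_complement(queries[0]))

    best: Optional[tuple[int, int]] = None  # (mismatches, position)
    skipped_n = False
    k = len(oligo.sequence)
    for q in queries:
        sets = [IUPAC_SETS[c] for c in q]
        for pos in range(len(t) - k + 1):
            window = t[pos : pos + k]
            if "N" in window:
                skipped_n = True
                continue
            mm = sum(base not in s for base, s in zip(window, sets))
            if best is None or mm < best[0]:
                best = (mm, pos)
    if best is not None and best[0] <= max_mismatches:
        return MatchReport(oligo.name, seq_id, best[0], best[1], skipped_n)
    return MatchReport(oligo.name, seq_id, None, None, skipped_n)


@dataclass
class CoverageResult:
    fraction: float
    hits: int
    misses: int
    excluded: int
    n_targets: int


def coverage(
    oligo: Oligo,
    targets: Iterable,
    max_mismatches: int = 0,
    orientation: str = "auto",
    n_policy: str = "sequence",
) -> CoverageResult:
    """Fraction of target sequences the oligo hits within the mismatch
    allowance, excluding N-containing sequences from the denominator.

    ``n_policy='sequence'`` (default) excludes any sequence containing an
    N, matching database probe-coverage practice; ``'window'`` only skips
    N-overlapping windows and keeps the sequence in the denominator.
    """
    targets = list(targets)
    if not targets:
        raise ValidationError("empty target collection")
    if n_policy not in ("sequence", "window"):
        raise ValidationError(f"unknown n_policy {n_policy!r}")
    hits = misses = excluded = 0
    for target in targets:
        seq_id, t = _target_id_seq(target)
        if n_policy == "sequence" and "N" in t:
            excluded += 1
            continue
        report = match_oligo(oligo, (seq_id, t), max_mismatches, orientation)
        if report.best_mismatches is not None:
            hits += 1
        else:
            misses += 1
    if hits + misses == 0:
        raise UndefinedResultError(
            "coverage undefined: every sequence was N-excluded"
        )
    return CoverageResult(
        fraction=hits / (hits + misses),
        hits=hits,
        misses=misses,
        excluded=excluded,
        n_targets=len(targets),
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped, mixed-case) multi-record FASTA as
    ``(id, sequence)`` pairs; the id is the token before the first
    whitespace."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records
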
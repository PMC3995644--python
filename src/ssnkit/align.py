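"""All-by-all pairwise local alignment with E-value statistics.

Each unordered sequence pair is scored once by optimal Smith-Waterman local
alignment with affine gaps (BLOSUM62, open 11 / extend 1 by default) and the
raw score converted to a bit score and E-value with the Karlin-Altschul
formula::

    S' = (lambda * S - ln K) / ln 2        E = m * n * 2**(-S')

where m and n are the two sequence lengths (the ``product_of_lengths``
search-space rule) or a fixed search space.  Alignments are computed with
Biopython's PairwiseAligner; a reader for 12-column tabular output of an
external search tool is provided as an alternative edge source, keeping the
lower E-value of the two search directions for each pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .records import InputError, SequenceRecord, check_unique_ids

__all__ = [
    "ScoringScheme",
    "PairSimilarity",
    "align_pair",
    "bit_score",
    "e_value",
    "all_by_all",
    "pairs_to_frame",
    "write_edge_table",
    "read_edge_table",
    "read_tabular_hits",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value statistics.

    ``lam`` (nats per score unit) and ``K`` default to the standard gapped
    BLOSUM62/11/1 constants.  ``gap_open`` is the gap existence penalty; a
    gap of length L costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    search_space: str = "product_of_lengths"  # or "fixed"
    fixed_space: float | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise InputError("lambda must be positive")
        if self.K <= 0:
            raise InputError("K must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise InputError("gap penalties must be nonnegative")
        if self.gap_extend > self.gap_open:
            raise InputError("gap_extend must not exceed gap_open")
        if self.search_space not in ("product_of_lengths", "fixed"):
            raise InputError("search_space must be 'product_of_lengths' or 'fixed'")
        if self.search_space == "fixed" and not self.fixed_space:
            raise InputError("fixed search space requires fixed_space")


@dataclass(frozen=True)
class PairSimilarity:
    """Best local-alignment similarity of one unordered sequence pair."""

    id_a: str
    id_b: str
    raw_score: int
    bit_score: float
    e_value: float
    identities: int
    alignment_length: int

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise InputError(f"self pair not allowed: {self.id_a!r}")
        if not 0 <= self.identities <= self.alignment_length:
            raise InputError("identities must be between 0 and alignment_length")
        if self.e_value < 0:
            raise InputError("e_value must be nonnegative")

    @property
    def percent_identity(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.identities / self.alignment_length

    @property
    def identity_fraction(self) -> float:
        return self.percent_identity / 100.0

    def key(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    aligner.mode = "local"
    # PairwiseAligner charges open_gap_score for the first gap position, so a
    # length-L gap under the existence/extension convention costs
    # gap_open + L * gap_extend == (open+extend) + (L-1) * extend.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalized (bit) score: (lambda*S - ln K) / ln 2."""
    return (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)


def e_value(raw_score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Expected number of chance alignments scoring >= raw_score.

    Strictly decreasing in raw_score; linear in the m*n search space under
    the ``product_of_lengths`` rule.
    """
    if m < 1 or n < 1:
        raise InputError("sequence lengths must be >= 1")
    if scheme.search_space == "fixed":
        space = float(scheme.fixed_space)
    else:
        space = float(m) * float(n)
    return space * math.pow(2.0, -bit_score(raw_score, scheme))


def align_pair(a: SequenceRecord, b: SequenceRecord,
               scheme: ScoringScheme = ScoringScheme()) -> PairSimilarity:
    """Optimal local alignment of one pair; symmetric under argument swap."""
    if a.id == b.id:
        raise InputError(f"cannot align a sequence with itself: {a.id!r}")
    # Canonical orientation so ties in the optimal-alignment traceback cannot
    # depend on argument order.
    first, second = (a, b) if a.id <= b.id else (b, a)
    aligner = _aligner(scheme)
    raw = aligner.score(first.sequence, second.sequence)
    if raw <= 0:
        identities, length = 0, 0
        raw = 0.0
    else:
        aln = aligner.align(first.sequence, second.sequence)[0]
        counts = aln.counts()
        identities = int(counts.identities)
        length = int(counts.identities + counts.mismatches + counts.gaps)
    return PairSimilarity(
        id_a=first.id,
        id_b=second.id,
        raw_score=int(round(raw)),
        bit_score=bit_score(raw, scheme),
        e_value=e_value(raw, len(a), len(b), scheme),
        identities=identities,
        alignment_length=length,
    )


def all_by_all(sequences, scheme: ScoringScheme = ScoringScheme(),
               report_ceiling: float = 10.0):
    """One PairSimilarity per unordered pair with E-value <= report_ceiling.

    The default ceiling of 10 mirrors the standard reporting behaviour of
    external search tools; pairs scoring worse never enter the edge list.
    """
    sequences = list(sequences)
    if len(sequences) < 2:
        raise InputError("all_by_all requires at least 2 sequences")
    check_unique_ids(sequences)
    aligner = _aligner(scheme)
    out = []
    for a, b in combinations(sequences, 2):
        first, second = (a, b) if a.id <= b.id else (b, a)
        raw = aligner.score(first.sequence, second.sequence)
        if raw <= 0:
            continue
        ev = e_value(raw, len(a), len(b), scheme)
        if ev > report_ceiling:
            continue
        aln = aligner.align(first.sequence, second.sequence)[0]
        counts = aln.counts()
        out.append(
            PairSimilarity(
                id_a=first.id,
                id_b=second.id,
                raw_score=int(round(raw)),
                bit_score=bit_score(raw, scheme),
                e_value=ev,
                identities=int(counts.identities),
                alignment_length=int(counts.identities + counts.mismatches + counts.gaps),
            )
        )
    return out


_EDGE_COLUMNS = [
    "id_a", "id_b", "raw_score", "bit_score", "e_value",
    "identities", "alignment_length",
]


def pairs_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.id_a, p.id_b, p.raw_score, p.bit_score, p.e_value,
          p.identities, p.alignment_length) for p in pairs],
        columns=_EDGE_COLUMNS,
    )


def write_edge_table(pairs, path) -> None:
    """Tab-separated edge list; E-values in scientific notation (>=3 sig digits)."""
    df = pairs_to_frame(pairs)
    df["bit_score"] = df["bit_score"].map(lambda v: f"{v:.2f}")
    df["e_value"] = df["e_value"].map(lambda v: f"{v:.3e}")
    df.to_csv(path, sep="\t", index=False)


def read_edge_table(path):
    df = pd.read_csv(path, sep="\t")
    missing = set(_EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"edge table missing columns: {sorted(missing)}")
    return [
        PairSimilarity(
            id_a=str(r.id_a), id_b=str(r.id_b), raw_score=int(r.raw_score),
            bit_score=float(r.bit_score), e_value=float(r.e_value),
            identities=int(r.identities), alignment_length=int(r.alignment_length),
        )
        for r in df.itertuples(index=False)
    ]


def read_tabular_hits(path, scheme: ScoringScheme = ScoringScheme()):
    """Read 12-column tabular output of an external all-by-all search.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, qstart, qend, sstart, send, e-value, bit score.  Self hits are
    dropped; for each unordered pair the hit with the lower E-value of the
    two search directions is kept (the best score between the pair).  The raw
    score is back-computed from the bit score under ``scheme``.
    """
    names = ["query", "subject", "pident", "length", "mismatch", "gapopen",
             "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    best = {}
    for r in df.itertuples(index=False):
        qa, sb = str(r.query), str(r.subject)
        if qa == sb:
            continue
        key = frozenset((qa, sb))
        if key not in best or float(r.evalue) < best[key][0]:
            best[key] = (float(r.evalue), r)
    out = []
    for key, (_ev, r) in sorted(best.items(), key=lambda kv: tuple(sorted(kv[0]))):
        id_a, id_b = sorted(key)
        length = int(r.length)
        identities = int(round(float(r.pident) * length / 100.0))
        raw = (float(r.bitscore) * math.log(2.0) + math.log(scheme.K)) / scheme.lam
        out.append(
            PairSimilarity(
                id_a=id_a, id_b=id_b, raw_score=int(round(raw)),
                bit_score=float(r.bitscore), e_value=float(r.evalue),
                identities=identities, alignment_length=length,
            )
        )
    return out
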
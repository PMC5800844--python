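"""Reciprocal-best-hit (RBH) homolog selection from BLAST tabular output.

Candidate homologs of a query protein (typically a human, mouse or fly
protein of characterised function) are retained when the query and subject
are each other's top-scoring match in mutual blastp searches, after an
e-value cutoff.  The searches themselves are external; this module consumes
their 12-column tabular output (``-outfmt 6``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "HitRecord",
    "RbhPair",
    "read_blast_tab",
    "filter_by_evalue",
    "best_hit_per_query",
    "reciprocal_best_hits",
    "write_rbh_tsv",
]

#: Default e-value cutoff for candidate homolog selection (inclusive).
DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class HitRecord:
    """One high-scoring pair from BLAST tabular (outfmt 6) output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")


@dataclass(frozen=True)
class RbhPair:
    """A reciprocal best hit between two proteomes (unordered pair)."""

    gene_a: str
    gene_b: str
    forward_bitscore: float
    reverse_bitscore: float

    @property
    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


def read_blast_tab(path: str | Path) -> list[HitRecord]:
    """Parse a BLAST tabular (outfmt 6) file into :class:`HitRecord` rows.

    Comment lines starting with ``#`` are skipped.  Any data line with a
    field count other than 12 raises :class:`ValueError` naming the line.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"fields, found {len(fields)}"
                )
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return hits


def filter_by_evalue(
    hits: Iterable[HitRecord], e_max: float = DEFAULT_EVALUE_MAX
) -> list[HitRecord]:
    """Retain hits with ``evalue <= e_max`` (inclusive cutoff)."""
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    return [h for h in hits if h.evalue <= e_max]


def _collapse_hsps(hits: Iterable[HitRecord]) -> dict[tuple[str, str], HitRecord]:
    """Keep the single best HSP per (query, subject) pair.

    The reciprocal criterion operates at gene level, so multiple HSPs for
    the same pair are collapsed to the one with the highest bitscore
    (ties: smaller e-value).
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
            best[key] = h
    return best


def best_hit_per_query(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Map each query to its top subject hit.

    Ranking is by bitscore (descending), then e-value (ascending), then
    subject id (lexicographic) so the result is deterministic.
    """
    collapsed = _collapse_hsps(hits)
    best: dict[str, HitRecord] = {}
    for h in collapsed.values():
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        if (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    forward: Mapping[str, HitRecord], reverse: Mapping[str, HitRecord]
) -> set[RbhPair]:
    """Pairs (q, s) where forward best of q is s and reverse best of s is q.

    The result is symmetric in its inputs: swapping forward and reverse
    yields the same unordered pair set.
    """
    pairs: dict[frozenset, RbhPair] = {}
    for q, fh in forward.items():
        s = fh.subject_id
        rh = reverse.get(s)
        if rh is not None and rh.subject_id == q:
            pair = RbhPair(
                gene_a=min(q, s),
                gene_b=max(q, s),
                forward_bitscore=fh.bitscore,
                reverse_bitscore=rh.bitscore,
            )
            pairs[pair.key] = pair
    return set(pairs.values())


def write_rbh_tsv(pairs: Iterable[RbhPair], path: str | Path) -> None:
    """Write RBH pairs as TSV (gene_a, gene_b, forward_bitscore, reverse_bitscore)."""
    rows = sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tforward_bitscore\treverse_bitscore\n")
        for p in rows:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.forward_bitscore:g}\t{p.reverse_bitscore:g}\n"
            )
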
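"""Domain-annotation tables, significance cutoffs and bHLH-PAS architectures.

Reads per-domain hits either from HMMER3 ``--domtblout`` output or from a
simplified TSV, applies the e-value/bitscore significance cutoffs used for
PFAM annotation of the bHLH-PAS family (e-value ≤ 0.1 and bitscore ≥ 10),
resolves overlapping hits, recognises the bHLH+PAS domain combination, and
delimits the C-terminal region downstream of the last PAS/PAC domain — the
region scanned for ODD-degron motifs.

Coordinates are converted on input from the 1-based inclusive convention of
HMMER tables to 0-based half-open intervals, and converted back on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DomainHit",
    "Architecture",
    "read_domtblout",
    "read_domain_tsv",
    "write_domain_tsv",
    "filter_domains",
    "resolve_overlaps",
    "group_architectures",
    "is_bhlh_pas",
    "cterm_region",
    "DEFAULT_DOMAIN_VOCAB",
    "NoPasDomainError",
]

#: PFAM models that tile canonical bHLH-PAS proteins; configurable because
#: the exact accession set counted as "PAS" varies between annotations.
DEFAULT_DOMAIN_VOCAB: dict[str, str] = {
    "HLH": "bHLH-class",
    "PAS": "PAS-class",
    "PAS_3": "PAS-class",
    "PAS_11": "PAS-class",
    "PAC": "PAS-class",
}

DEFAULT_EVALUE_MAX = 0.1
DEFAULT_SCORE_MIN = 10.0


class NoPasDomainError(ValueError):
    """Raised when a C-terminal region is requested for a protein without a
    PAS-class domain; callers wanting a full-sequence scan must ask for it
    explicitly."""


@dataclass(frozen=True)
class DomainHit:
    """One domain hit; ``start``/``end`` are 0-based half-open."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: empty or inverted "
                f"interval [{self.start}, {self.end})"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Architecture:
    """Ordered, non-overlapping domain hits of one protein."""

    protein_id: str
    hits: tuple[DomainHit, ...]
    protein_length: Optional[int] = None

    def __post_init__(self) -> None:
        starts = [h.start for h in self.hits]
        if starts != sorted(starts):
            raise ValueError("architecture hits must be sorted by start")


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse HMMER3 ``--domtblout`` per-domain output.

    Uses the envelope coordinates (columns 20–21, 1-based inclusive) and
    the per-domain independent e-value and bitscore.  The trailing
    free-text description may contain whitespace and is ignored.  In
    hmmsearch orientation the target is the protein and the query the
    profile.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 22 whitespace-"
                    f"separated fields, found {len(fields)}"
                )
            env_from = int(fields[19])
            env_to = int(fields[20])
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    domain_name=fields[3],
                    start=env_from - 1,  # 1-based inclusive -> 0-based half-open
                    end=env_to,
                    evalue=float(fields[12]),
                    bitscore=float(fields[13]),
                )
            )
    return hits


def read_domain_tsv(path: str | Path) -> list[DomainHit]:
    """Read the simplified domain TSV (1-based inclusive coordinates).

    Columns: protein_id, domain_name, start, end, evalue, bitscore, with a
    header line.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id\t"):
            raise ValueError(f"{path}: missing domain TSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 fields, found "
                    f"{len(fields)}"
                )
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    domain_name=fields[1],
                    start=int(fields[2]) - 1,
                    end=int(fields[3]),
                    evalue=float(fields[4]),
                    bitscore=float(fields[5]),
                )
            )
    return hits


def write_domain_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the simplified TSV format (back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain_name\tstart\tend\tevalue\tbitscore\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.domain_name}\t{h.start + 1}\t{h.end}"
                f"\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


def filter_domains(
    hits: Iterable[DomainHit],
    e_max: float = DEFAULT_EVALUE_MAX,
    score_min: float = DEFAULT_SCORE_MIN,
) -> list[DomainHit]:
    """Keep hits with evalue ≤ e_max and bitscore ≥ score_min (idempotent)."""
    if e_max <= 0 or score_min <= 0:
        raise ValueError("thresholds must be positive")
    return [h for h in hits if h.evalue <= e_max and h.bitscore >= score_min]


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy overlap resolution for the hits of a single protein.

    Hits are accepted in order of decreasing bitscore (ties: earlier start
    first); a candidate is dropped when it overlaps an accepted hit by more
    than 50% of the shorter of the two.
    """
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(protein_ids)}")
    ranked = sorted(hits, key=lambda h: (-h.bitscore, h.start, h.domain_name))
    accepted: list[DomainHit] = []
    for h in ranked:
        clash = any(
            _overlap(h, a) > 0.5 * min(h.length, a.length) for a in accepted
        )
        if not clash:
            accepted.append(h)
    return sorted(accepted, key=lambda h: h.start)


def group_architectures(
    hits: Iterable[DomainHit],
    protein_lengths: Optional[Mapping[str, int]] = None,
) -> dict[str, Architecture]:
    """Group filtered hits by protein and resolve overlaps per protein."""
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    return {
        pid: Architecture(
            protein_id=pid,
            hits=tuple(resolve_overlaps(prot_hits)),
            protein_length=(
                protein_lengths.get(pid) if protein_lengths else None
            ),
        )
        for pid, prot_hits in by_protein.items()
    }


def is_bhlh_pas(
    arch: Architecture,
    domain_vocab: Mapping[str, str] = DEFAULT_DOMAIN_VOCAB,
    require_order: bool = True,
) -> bool:
    """True iff the protein carries the bHLH+PAS domain combination.

    Requires ≥1 bHLH-class and ≥1 PAS-class domain; by default the bHLH
    domain must lie N-terminal to the first PAS-class domain, matching the
    canonical family architecture (relaxable via ``require_order``).
    """
    if not domain_vocab:
        raise ValueError("empty domain vocabulary")
    bhlh = [
        h for h in arch.hits if domain_vocab.get(h.domain_name) == "bHLH-class"
    ]
    pas = [
        h for h in arch.hits if domain_vocab.get(h.domain_name) == "PAS-class"
    ]
    if not bhlh or not pas:
        return False
    if not require_order:
        return True
    first_pas_start = min(h.start for h in pas)
    return any(h.start < first_pas_start for h in bhlh)


def cterm_region(
    arch: Architecture,
    domain_vocab: Mapping[str, str] = DEFAULT_DOMAIN_VOCAB,
) -> tuple[int, int]:
    """C-terminal region from the end of the last PAS/PAC domain to the end.

    Returns a 0-based half-open interval; the empty interval is legitimate
    when the last PAS-class domain reaches the protein end.  Raises
    :class:`NoPasDomainError` for proteins without any PAS-class domain —
    scanning the full sequence must then be an explicit caller choice.
    """
    if not arch.hits:
        raise ValueError(f"{arch.protein_id}: architecture has no domains")
    if arch.protein_length is None:
        raise ValueError(f"{arch.protein_id}: protein length unknown")
    pas = [
        h for h in arch.hits if domain_vocab.get(h.domain_name) == "PAS-class"
    ]
    if not pas:
        raise NoPasDomainError(
            f"{arch.protein_id}: no PAS-class domain; scan the full sequence "
            "explicitly if intended"
        )
    start = max(h.end for h in pas)
    return (start, arch.protein_length)
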
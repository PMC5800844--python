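"""ODD-degron motif scanning with composition-based chance-occurrence nulls.

The oxygen-dependent degradation (ODD) region of HIFa contains the octamer
consensus L[D/E]x[L/R]AP[F/Y]I around the hydroxyl-acceptor proline.  The
tetramer at consensus positions 4–7 varies between clades — LAPY in
vertebrates, RAPY in most protostomes, RAPY/RAPF in cnidarians, LAPF in
placozoans — so two scan modes are exposed:

* strict — the full 8-position consensus;
* core — the [L/R]AP[F/Y] tetramer only, which also captures near-miss
  cases such as the ctenophore LAMRAPYI octamer.

Because the C-terminal tails of bHLH-PAS proteins are proline/serine/
glutamine-rich, short LAP/RAP-type matches arise by chance; the module
quantifies that both analytically (expected count under an i.i.d. residue
model with the region's composition) and empirically (within-region
permutation test, which preserves composition exactly).

Coordinates are 0-based half-open internally; report writers print 1-based.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "MotifHit",
    "CompositionStats",
    "scan_motif",
    "composition",
    "expected_motif_count",
    "motif_permutation_pvalue",
    "write_hits_tsv",
    "STRICT_PATTERN",
    "CORE_PATTERN",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY" + "X*")

#: pattern position -> allowed residues; None = any residue
STRICT_PATTERN: tuple[Optional[str], ...] = (
    "L", "DE", None, "LR", "A", "P", "FY", "I",
)
CORE_PATTERN: tuple[Optional[str], ...] = ("LR", "A", "P", "FY")

_STRICT_RE = re.compile(r"(?=(L[DE].[LR]AP[FY]I))")
_CORE_RE = re.compile(r"(?=([LR]AP[FY]))")

#: offset of the variant tetramer within a strict octamer
_VARIANT_OFFSET = 3


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence within the scanned region.

    ``start`` is 0-based relative to the scanned region; ``match`` is the
    full octamer (strict mode) or the tetramer (core mode); ``variant`` is
    the clade-diagnostic tetramer (LAPY, RAPY, RAPF or LAPF).
    """

    protein_id: str
    start: int
    match: str
    mode: str
    variant: str


@dataclass(frozen=True)
class CompositionStats:
    """Residue composition of a scanned region."""

    length: int
    frequencies: dict[str, float]

    @property
    def psq_fraction(self) -> float:
        """Combined proline+serine+glutamine fraction (tail enrichment)."""
        return sum(self.frequencies.get(a, 0.0) for a in "PSQ")


def _check_sequence(seq: str) -> None:
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residue characters: {sorted(bad)}")


def _pattern_for(mode: str):
    if mode == "strict":
        return _STRICT_RE, STRICT_PATTERN
    if mode == "core":
        return _CORE_RE, CORE_PATTERN
    raise ValueError(f"unknown scan mode {mode!r}")


def scan_motif(
    sequence: str,
    region: Optional[tuple[int, int]] = None,
    mode: str = "strict",
    protein_id: str = "",
) -> list[MotifHit]:
    """Find all (possibly overlapping) motif matches within a region.

    ``region`` is 0-based half-open within ``sequence`` (default: the whole
    sequence); hit starts are relative to the region and sorted ascending.
    """
    _check_sequence(sequence)
    lo, hi = region if region is not None else (0, len(sequence))
    if not (0 <= lo <= hi <= len(sequence)):
        raise ValueError(f"region ({lo}, {hi}) outside sequence")
    text = sequence[lo:hi]
    regex, _ = _pattern_for(mode)
    hits = []
    for m in regex.finditer(text):
        match = m.group(1)
        variant = (
            match[_VARIANT_OFFSET : _VARIANT_OFFSET + 4]
            if mode == "strict"
            else match
        )
        hits.append(
            MotifHit(
                protein_id=protein_id,
                start=m.start(),
                match=match,
                mode=mode,
                variant=variant,
            )
        )
    return hits


def composition(
    sequence: str, region: Optional[tuple[int, int]] = None
) -> CompositionStats:
    """Exact residue frequencies of a region (empty region → length 0)."""
    _check_sequence(sequence)
    lo, hi = region if region is not None else (0, len(sequence))
    if not (0 <= lo <= hi <= len(sequence)):
        raise ValueError(f"region ({lo}, {hi}) outside sequence")
    text = sequence[lo:hi]
    n = len(text)
    if n == 0:
        return CompositionStats(length=0, frequencies={})
    counts: dict[str, int] = {}
    for a in text:
        counts[a] = counts.get(a, 0) + 1
    return CompositionStats(
        length=n, frequencies={a: c / n for a, c in counts.items()}
    )


def expected_motif_count(stats: CompositionStats, mode: str = "strict") -> float:
    """Expected number of matches under an i.i.d. residue model.

    E = (L − k + 1) · Π_positions (Σ allowed-residue frequencies), with a
    free ('any') position contributing factor 1.  Returns 0 when the region
    is shorter than the pattern.
    """
    _, pattern = _pattern_for(mode)
    k = len(pattern)
    if stats.length < k:
        return 0.0
    per_window = 1.0
    for allowed in pattern:
        if allowed is None:
            continue
        per_window *= sum(stats.frequencies.get(a, 0.0) for a in allowed)
    return (stats.length - k + 1) * per_window


def motif_permutation_pvalue(
    sequence: str,
    region: Optional[tuple[int, int]] = None,
    mode: str = "strict",
    n_shuffles: int = 999,
    seed: int = 0,
) -> tuple[float, int]:
    """Permutation p-value for the observed match count in a region.

    Residues of the region are shuffled uniformly ``n_shuffles`` times;
    p = (1 + #{shuffles with count ≥ observed}) / (n_shuffles + 1).  The
    shuffle null preserves composition exactly (but not residue runs).
    Returns (p, observed_count).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    lo, hi = region if region is not None else (0, len(sequence))
    observed = len(scan_motif(sequence, (lo, hi), mode))
    residues = list(sequence[lo:hi])
    rng = random.Random(seed)
    regex, _ = _pattern_for(mode)
    at_least = 0
    for _ in range(n_shuffles):
        rng.shuffle(residues)
        count = sum(1 for _ in regex.finditer("".join(residues)))
        if count >= observed:
            at_least += 1
    return (1 + at_least) / (n_shuffles + 1), observed


def write_hits_tsv(hits: Iterable[MotifHit], path) -> None:
    """Write hits as TSV with 1-based start positions."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart_1based\tmatch\tmode\tvariant\n")
        for h in sorted(hits, key=lambda h: (h.protein_id, h.start)):
            fh.write(
                f"{h.protein_id}\t{h.start + 1}\t{h.match}\t{h.mode}"
                f"\t{h.variant}\n"
            )
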
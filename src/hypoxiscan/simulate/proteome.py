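"""Synthetic proteomes with bHLH+PAS architectures and planted ODD motifs.

Each protein is assembled from an ordered series of domains (annotated in a
companion TSV) followed by a disordered C-terminal tail drawn from a
proline/serine/glutamine-rich residue composition.  Strict degron octamers
can be planted at chosen tail offsets; the generator scrubs any *chance*
strict match so the truth record lists exactly the planted instances, while
the composition-driven background (including chance core tetramers) is left
in place.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["ProteinPlan", "ProteomePlan", "ProteinTruth", "simulate_proteome"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_STRICT_RE = re.compile(r"(?=(L[DE].[LR]AP[FY]I))")

#: P/S/Q-rich default tail composition; remaining mass spread uniformly.
def _default_tail_composition() -> dict[str, float]:
    comp = {"P": 0.20, "S": 0.15, "Q": 0.10}
    rest = [a for a in AMINO_ACIDS if a not in comp]
    for a in rest:
        comp[a] = 0.55 / len(rest)
    return comp


@dataclass
class ProteinPlan:
    """Architecture plan for one synthetic protein."""

    protein_id: str
    #: ordered (domain_name, length) pairs, N- to C-terminal
    domains: tuple[tuple[str, int], ...] = (
        ("HLH", 55),
        ("PAS", 70),
        ("PAS_3", 65),
        ("PAC", 45),
    )
    linker_length: int = 15
    leader_length: int = 12
    tail_length: int = 200
    tail_composition: Optional[dict[str, float]] = None
    #: (offset within tail, octamer) pairs
    planted_motifs: tuple[tuple[int, str], ...] = ()


@dataclass
class ProteomePlan:
    proteins: tuple[ProteinPlan, ...]


@dataclass
class ProteinTruth:
    protein_id: str
    sequence: str
    #: 0-based half-open domain intervals, in order
    domain_intervals: tuple[tuple[str, int, int], ...]
    #: 0-based half-open tail interval (may be empty)
    tail_interval: tuple[int, int]
    #: absolute 0-based starts of planted strict motifs
    planted_positions: tuple[int, ...]
    tail_counts: dict[str, int] = field(default_factory=dict)


def _draw(rng: random.Random, comp_letters: list[str], comp_cum: list[float]) -> str:
    x = rng.random()
    for letter, c in zip(comp_letters, comp_cum):
        if x <= c:
            return letter
    return comp_letters[-1]


def _sample_seq(rng: random.Random, n: int, comp: dict[str, float]) -> list[str]:
    letters = sorted(comp)
    cum: list[float] = []
    total = 0.0
    for a in letters:
        total += comp[a]
        cum.append(total)
    return [_draw(rng, letters, cum) for _ in range(n)]


def _scrub_chance_strict(
    seq: list[str],
    protected: set[int],
    rng: random.Random,
    comp: dict[str, float],
    lo: int,
    hi: int,
) -> None:
    """Resample any chance strict octamer in seq[lo:hi] not at a protected start."""
    for _ in range(200):
        text = "".join(seq)
        chance = [
            m.start()
            for m in _STRICT_RE.finditer(text)
            if m.start() not in protected
        ]
        chance = [p for p in chance if lo <= p]
        if not chance:
            return
        for p in chance:
            for i in range(p, min(p + 8, len(seq))):
                if not any(q <= i < q + 8 for q in protected):
                    seq[i] = _sample_seq(rng, 1, comp)[0]
    raise RuntimeError("could not scrub chance strict motifs")


def simulate_proteome(
    plan: ProteomePlan, seed: int
) -> tuple[str, str, dict[str, ProteinTruth]]:
    """Generate FASTA text, a domain TSV, and per-protein truth records.

    The domain TSV uses 1-based inclusive coordinates (HMMER convention):
    columns protein_id, domain_name, start, end, evalue, bitscore.
    """
    rng = random.Random(seed)
    uniform = {a: 1.0 / 20.0 for a in AMINO_ACIDS}
    fasta_parts: list[str] = []
    tsv_rows: list[str] = []
    truths: dict[str, ProteinTruth] = {}
    for prot in plan.proteins:
        tail_comp = prot.tail_composition or _default_tail_composition()
        total = sum(tail_comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{prot.protein_id}: tail composition sums to {total}, not 1"
            )
        seq: list[str] = []
        seq.extend(_sample_seq(rng, prot.leader_length, uniform))
        intervals: list[tuple[str, int, int]] = []
        for i, (name, length) in enumerate(prot.domains):
            if i > 0:
                seq.extend(_sample_seq(rng, prot.linker_length, uniform))
            start = len(seq)
            seq.extend(_sample_seq(rng, length, uniform))
            intervals.append((name, start, len(seq)))
        tail_start = len(seq)
        seq.extend(_sample_seq(rng, prot.tail_length, tail_comp))
        tail_end = len(seq)

        planted_abs: list[int] = []
        for offset, octamer in prot.planted_motifs:
            if re.fullmatch(r"L[DE].[LR]AP[FY]I", octamer) is None:
                raise ValueError(
                    f"{prot.protein_id}: {octamer!r} is not a strict octamer"
                )
            if offset < 0 or offset + 8 > prot.tail_length:
                raise ValueError(
                    f"{prot.protein_id}: plant at tail offset {offset} falls "
                    "outside the tail (would overlap a domain or run off the end)"
                )
            pos = tail_start + offset
            seq[pos : pos + 8] = list(octamer)
            planted_abs.append(pos)
        if len(set(planted_abs)) != len(planted_abs):
            raise ValueError(f"{prot.protein_id}: duplicate plant offsets")

        _scrub_chance_strict(seq, set(planted_abs), rng, tail_comp, 0, len(seq))

        text = "".join(seq)
        tail_counts: dict[str, int] = {}
        for a in text[tail_start:tail_end]:
            tail_counts[a] = tail_counts.get(a, 0) + 1

        fasta_parts.append(f">{prot.protein_id}")
        for i in range(0, len(text), 60):
            fasta_parts.append(text[i : i + 60])
        for name, s0, e0 in intervals:
            tsv_rows.append(
                f"{prot.protein_id}\t{name}\t{s0 + 1}\t{e0}\t1e-20\t80.0"
            )
        truths[prot.protein_id] = ProteinTruth(
            protein_id=prot.protein_id,
            sequence=text,
            domain_intervals=tuple(intervals),
            tail_interval=(tail_start, tail_end),
            planted_positions=tuple(planted_abs),
            tail_counts=tail_counts,
        )
    fasta = "\n".join(fasta_parts) + ("\n" if fasta_parts else "")
    tsv = (
        "protein_id\tdomain_name\tstart\tend\tevalue\tbitscore\n"
        + "\n".join(tsv_rows)
        + ("\n" if tsv_rows else "")
    )
    return fasta, tsv, truths
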
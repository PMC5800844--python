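"""Synthetic BLAST tabular (outfmt 6) tables for two proteomes.

For each simulated family, every gene of the query species is scored
against every gene of the subject species (and vice versa for the reverse
table).  Bitscores are a strictly decreasing function of gene-tree
patristic distance plus seeded jitter bounded so that the ranking of
distinct distances is never reordered; e-values decrease monotonically
with bitscore.  Under this construction, on duplication-free families the
reciprocal-best-hit set equals the true 1:1 ortholog pairs.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Iterable, Optional, Sequence

from hypoxiscan.simulate.genefam import FamilyTruth, patristic_distances

__all__ = ["simulate_blast_tables"]


def _species_of(gene: str) -> str:
    return gene.split("|", 1)[0]


def _bitscore_base(distance: float) -> float:
    # strictly decreasing, bounded in (0, 500]
    return 500.0 / (1.0 + distance)


def _format_row(q: str, s: str, distance: float, bitscore: float) -> str:
    pident = max(15.0, 100.0 - 18.0 * distance)
    length = 220
    mism = int(round(length * (100.0 - pident) / 100.0))
    evalue = 10.0 ** (-bitscore / 10.0)
    return (
        f"{q}\t{s}\t{pident:.1f}\t{length}\t{mism}\t0\t1\t{length}\t1\t{length}"
        f"\t{evalue:.2e}\t{bitscore:.1f}"
    )


def simulate_blast_tables(
    families: Sequence[FamilyTruth],
    seed: int,
    query_species: str,
    subject_species: str,
    forward_path: Optional[str | Path] = None,
    reverse_path: Optional[str | Path] = None,
) -> tuple[str, str]:
    """Emit forward (query→subject) and reverse (subject→query) tables.

    Returns the two tables as text; optionally also writes them.  An empty
    family list (or families with no genes in either species) yields empty
    tables.
    """
    rng = random.Random(seed)
    fwd_rows: list[str] = []
    rev_rows: list[str] = []
    for fam in families:
        if fam.extinct:
            continue
        dists = patristic_distances(fam)
        q_genes = [g for g in fam.genes() if _species_of(g) == query_species]
        s_genes = [g for g in fam.genes() if _species_of(g) == subject_species]
        if not q_genes or not s_genes:
            continue
        pairs = [(q, s) for q in q_genes for s in s_genes]
        bases = {p: _bitscore_base(dists[frozenset(p)]) for p in pairs}
        distinct = sorted(set(bases.values()))
        gaps = [b - a for a, b in zip(distinct, distinct[1:])]
        # jitter bounded below half the smallest gap between distinct base
        # scores: ranks of distinct distances can never be reordered
        jmax = min(gaps) / 3.0 if gaps else 0.5
        for q, s in pairs:
            fwd_rows.append(
                _format_row(q, s, dists[frozenset((q, s))],
                            bases[(q, s)] + rng.uniform(-jmax, jmax))
            )
            rev_rows.append(
                _format_row(s, q, dists[frozenset((q, s))],
                            bases[(q, s)] + rng.uniform(-jmax, jmax))
            )
    forward = "\n".join(fwd_rows) + ("\n" if fwd_rows else "")
    reverse = "\n".join(rev_rows) + ("\n" if rev_rows else "")
    if forward_path is not None:
        Path(forward_path).write_text(forward)
    if reverse_path is not None:
        Path(reverse_path).write_text(reverse)
    return forward, reverse
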
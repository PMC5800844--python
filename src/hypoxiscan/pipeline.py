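"""End-to-end orchestration, DE-table thresholding and run provenance.

Chains the comparative stages (gene trees → event labelling → per-clade
verdicts → secondary-loss upgrade → presence–absence matrix) and the
physiological stages (area traces → contraction events → Poisson rate
model → contraction-coupled uptake).  Also provides the Benjamini–Hochberg
step-up adjustment and the published-threshold filter used to summarise
externally produced differential-expression tables; the DE testing itself
(negative-binomial modelling) is an external-tool step and is deliberately
not reimplemented here.

Every report dict embeds a short hash of the parameters that produced it,
so outputs can be traced back to their configuration.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from hypoxiscan import orthology
from hypoxiscan.orthology import OrthologyCall
from hypoxiscan.physiology import (
    ContractionEvent,
    DetectorConfig,
    contraction_rate,
    detect_contractions,
    fit_rate_model,
    phase_coupled_uptake,
    respiration_rate,
)

__all__ = [
    "bh_adjust",
    "filter_de_table",
    "read_species_map",
    "run_comparative",
    "run_physiology",
    "config_hash",
    "PORIFERA_SISTER_ORDER",
    "CTENOPHORA_SISTER_ORDER",
]

#: Clade column orders for the two presentation topologies; verdicts are
#: identical, only the column order differs.
PORIFERA_SISTER_ORDER = (
    "Bilateria",
    "Cnidaria",
    "Placozoa",
    "Ctenophora",
    "Calcarea",
    "Demospongiae",
    "Hexactinellida",
    "Homoscleromorpha",
    "Choanoflagellata",
    "Capsaspora",
)
CTENOPHORA_SISTER_ORDER = (
    "Bilateria",
    "Cnidaria",
    "Placozoa",
    "Calcarea",
    "Demospongiae",
    "Hexactinellida",
    "Homoscleromorpha",
    "Ctenophora",
    "Choanoflagellata",
    "Capsaspora",
)


def config_hash(params: Mapping) -> str:
    """Short stable hash of a parameter mapping, for run provenance."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# DE-table thresholding


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending, set adj_i = min_{j >= i} (m * p_(j)) / j capped at 1,
    and return the adjusted values in the original input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def filter_de_table(
    records: pd.DataFrame,
    alpha: float = 0.01,
    lfc: float = 2.0,
) -> dict[str, set[str]]:
    """Split a DE table into over-/under-expressed gene sets.

    ``records`` needs columns (gene_id, log2_fold_change) and either
    p_adjusted or p_value (adjusted in-place by BH when only raw p-values
    are present).  Overexpressed: adjusted p < alpha and LFC >= lfc;
    underexpressed: adjusted p < alpha and LFC <= -lfc — the fold-change
    bounds are inclusive, the significance bound strict, matching the
    printed comparison symbols.
    """
    df = records.copy()
    if "p_adjusted" not in df.columns:
        if "p_value" not in df.columns:
            raise ValueError("records need p_adjusted or p_value")
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    sig = df["p_adjusted"] < alpha
    over = set(df.loc[sig & (df["log2_fold_change"] >= lfc), "gene_id"])
    under = set(df.loc[sig & (df["log2_fold_change"] <= -lfc), "gene_id"])
    return {"overexpressed": over, "underexpressed": under}


# ---------------------------------------------------------------------------
# comparative pipeline


def read_species_map(path) -> dict[str, str]:
    """Read a species map TSV: (gene_prefix, species, clade) or (species, clade)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                _, species, clade = fields
            elif len(fields) == 2:
                species, clade = fields
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 or 3 fields"
                )
            out[species] = clade
    return out


def run_comparative(
    trees: Mapping[str, str],
    species_map: Mapping[str, str],
    references: Mapping[str, str],
    outgroup_clades: Sequence[str] = ("Choanoflagellata", "Capsaspora"),
    clades: Optional[Sequence[str]] = None,
    min_support: Optional[float] = None,
) -> dict:
    """Presence–absence profiling of pathway components across clades.

    ``trees`` maps component name to Newick text, ``references`` to the
    reference leaf (e.g. ``human|HIF1A``).  Missing inputs are enumerated
    before any computation.  The report carries the matrix rendered under
    both a Porifera-sister and a Ctenophora-sister clade ordering (pure
    presentation; the verdicts are identical).
    """
    problems = []
    if not trees:
        problems.append("no gene trees supplied")
    for comp in trees:
        if comp not in references:
            problems.append(f"component {comp!r}: no reference leaf configured")
    if not species_map:
        problems.append("species map is empty")
    if problems:
        raise ValueError("; ".join(problems))

    if clades is None:
        clades = list(dict.fromkeys(species_map.values()))
    for og in outgroup_clades:
        if og not in clades:
            raise ValueError(f"outgroup clade {og!r} not in clade set")

    outgroup_species = [
        s for s, c in species_map.items() if c in set(outgroup_clades)
    ]
    calls: list[OrthologyCall] = []
    verdicts: dict[tuple[str, str], str] = {}
    flags: dict[tuple[str, str], bool] = {}
    for comp, newick in trees.items():
        tree = orthology.read_newick(newick)
        orthology.root_tree(tree, outgroup_species)
        if min_support is not None:
            orthology.collapse_low_support(tree, min_support)
        orthology.label_events_species_overlap(tree, species_map)
        for clade in clades:
            members = [s for s, c in species_map.items() if c == clade]
            verdicts[(comp, clade)] = orthology.classify_clade(
                tree, references[comp], members
            )
            flags[(comp, clade)] = orthology.flag_lineage_duplications(
                tree, species_map, clade
            )
    for comp in trees:
        for clade in clades:
            upgraded = orthology.call_secondary_loss(
                comp, clade, verdicts, outgroup_clades
            )
            calls.append(
                OrthologyCall(
                    component=comp,
                    clade=clade,
                    verdict=upgraded,
                    lineage_dup_flag=flags[(comp, clade)],
                )
            )

    order_a = [c for c in PORIFERA_SISTER_ORDER if c in clades] + [
        c for c in clades if c not in PORIFERA_SISTER_ORDER
    ]
    order_b = [c for c in CTENOPHORA_SISTER_ORDER if c in clades] + [
        c for c in clades if c not in CTENOPHORA_SISTER_ORDER
    ]
    matrix_a = orthology.build_matrix(calls, clade_order=order_a)
    matrix_b = orthology.build_matrix(calls, clade_order=order_b)
    return {
        "calls": calls,
        "matrix_porifera_sister": matrix_a,
        "matrix_ctenophora_sister": matrix_b,
        "config_hash": config_hash(
            {
                "components": sorted(trees),
                "references": dict(references),
                "outgroups": list(outgroup_clades),
                "min_support": min_support,
            }
        ),
    }


# ---------------------------------------------------------------------------
# physiology pipeline


def run_physiology(
    area_traces: Mapping[str, pd.DataFrame],
    plateaus: Sequence[tuple[float, float, str]],
    o2_trace: Optional[pd.DataFrame] = None,
    detector: DetectorConfig = DetectorConfig(),
    class_filter: Optional[str] = "full_body",
    respiration_window: int = 21,
    seed: int = 0,
) -> dict:
    """Detection → per-plateau counts → rate model → optional O2 coupling.

    ``area_traces`` maps individual id to an area trace; ``plateaus`` lists
    (t_start_s, t_end_s, level_label) windows of stable O2.  When an O2
    trace is supplied, contraction-coupled uptake is quantified for the
    first individual's events.
    """
    if not area_traces:
        raise ValueError("no area traces supplied")
    if not plateaus:
        raise ValueError("no stable-O2 plateaus supplied")
    events_by_individual: dict[str, list[ContractionEvent]] = {}
    rows = []
    for indiv, trace in area_traces.items():
        events = detect_contractions(trace, detector)
        events_by_individual[indiv] = events
        for t0, t1, label in plateaus:
            n = sum(
                1
                for ev in events
                if t0 <= ev.trough_s < t1
                and (class_filter is None or ev.klass == class_filter)
            )
            rows.append(
                {
                    "individual": indiv,
                    "level": label,
                    "count": n,
                    "exposure_days": (t1 - t0) / 86400.0,
                    "rate_per_day": contraction_rate(
                        events, (t0, t1), class_filter
                    ),
                }
            )
    counts = pd.DataFrame(rows)
    model = None
    if counts["level"].nunique() >= 2:
        model = fit_rate_model(
            counts[["individual", "level", "count", "exposure_days"]]
        )
    coupling = None
    if o2_trace is not None:
        rates = respiration_rate(o2_trace, respiration_window)
        first = next(iter(area_traces))
        if events_by_individual[first]:
            coupling = phase_coupled_uptake(
                rates, events_by_individual[first], seed=seed
            )
    return {
        "events": events_by_individual,
        "counts": counts,
        "rate_model": model,
        "coupling": coupling,
        "config_hash": config_hash(
            {
                "plateaus": list(plateaus),
                "class_filter": class_filter,
                "theta_full": detector.theta_full,
                "theta_sub": detector.theta_sub,
                "seed": seed,
            }
        ),
    }
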
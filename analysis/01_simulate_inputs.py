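"""Generate the synthetic comparative and behavioural datasets.

Produces everything the downstream analyses consume, with truth records:
gene families evolved by duplication-loss on the opisthokont species tree,
forward/reverse homology-search tables between the human and Tethya
proteomes, a small bHLH-PAS proteome with planted and absent ODD motifs,
and a stepped low-oxygen contraction experiment (100 -> 10 -> 5 -> 2 ->
0.25 %AS) for three individuals in which full-body contractions cease
below 5 %AS.

Writes scratch/simulated/ (trees, tables, traces — regenerable
intermediates) and prints a summary of what was generated.
"""

import json
from pathlib import Path

from hypoxiscan.simulate import (
    ProteinPlan,
    ProteomePlan,
    default_species_tree,
    make_experiment_truth,
    simulate_blast_tables,
    simulate_experiment,
    simulate_gene_family,
    simulate_proteome,
)

SEED = 20260926
OUT = Path("scratch/simulated")

#: the stepped exposure schedule (hours, %AS) used throughout the analyses
SCHEDULE = ((24.0, 100.0), (24.0, 10.0), (20.0, 5.0), (20.0, 2.0), (20.0, 0.25))
#: full-body contraction rates per level: unchanged down to 5 %AS, ceasing
#: below; sub-contractions persist at the lowest levels
FULL_RATES = {100.0: 12.0, 10.0: 12.0, 5.0: 12.0, 2.0: 0.0, 0.25: 0.0}
SUB_RATES = {100.0: 0.0, 10.0: 0.0, 5.0: 0.0, 2.0: 4.0, 0.25: 4.0}

COMPONENTS = ("HIFa", "ARNT", "EGL9", "VHL", "FIH")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sp = default_species_tree()

    # --- gene families for five pathway components (one tree each) plus a
    # background set for the homology stage
    (OUT / "trees").mkdir(exist_ok=True)
    refs = {}
    for i, comp in enumerate(COMPONENTS):
        for attempt in range(50):
            fam = simulate_gene_family(
                sp, 0.08, 0.04, seed=SEED + 100 * i + attempt, family_id=comp
            )
            if not fam.extinct and any(
                g.startswith("human|") for g in fam.genes()
            ):
                break
        (OUT / "trees" / f"{comp}.nwk").write_text(fam.newick + "\n")
        refs[comp] = [g for g in fam.genes() if g.startswith("human|")][0]
    (OUT / "references.json").write_text(json.dumps(refs, indent=1))

    with open(OUT / "species_map.tsv", "w") as fh:
        for species, clade in sp.clades.items():
            fh.write(f"{species}\t{species}\t{clade}\n")

    background = [
        simulate_gene_family(sp, 0.0, 0.1, seed=SEED + 1000 + k)
        for k in range(120)
    ]
    simulate_blast_tables(
        background,
        seed=SEED,
        query_species="human",
        subject_species="tethya",
        forward_path=OUT / "blast_forward.tsv",
        reverse_path=OUT / "blast_reverse.tsv",
    )
    truth_pairs = sorted(
        tuple(sorted((a, b)))
        for fam in background
        for (a, b), rel in fam.relations.items()
        if a < b
        and rel == "1:1"
        and {a.split("|")[0], b.split("|")[0]} == {"human", "tethya"}
    )
    with open(OUT / "true_1to1_pairs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in truth_pairs:
            fh.write(f"{a}\t{b}\n")

    # --- proteome: a vertebrate-style HIFa with a planted LAPY degron, a
    # placozoan-style LAPF variant, a ctenophore protein that will carry a
    # core-only LAMRAPYI near-miss (spliced below), and sponge proteins
    # with P/S/Q-rich tails but no degron
    plan = ProteomePlan(
        proteins=(
            ProteinPlan("human|HIF1A", tail_length=400,
                        planted_motifs=((60, "LEMLAPYI"),)),
            ProteinPlan("trichoplax|HIFa", tail_length=300,
                        planted_motifs=((80, "LDQLAPFI"),)),
            ProteinPlan("euplokamis|bhlhpas", tail_length=350),
            ProteinPlan("tethya|bhlhpas1", tail_length=380),
            ProteinPlan("amphimedon|bhlhpas1", tail_length=420),
            ProteinPlan("human|NPAS3", tail_length=350),
        )
    )
    fasta, domain_tsv, truths = simulate_proteome(plan, seed=SEED)
    # splice the near-miss octamer (no strict match, core RAPY only) into
    # the ctenophore tail, mirroring a degron-like motif outside the
    # consensus; overwriting in place keeps all other coordinates valid
    ct = truths["euplokamis|bhlhpas"]
    pos = ct.tail_interval[0] + 120
    spliced = ct.sequence[:pos] + "LAMRAPYI" + ct.sequence[pos + 8 :]
    from hypoxiscan.motifs import scan_motif

    assert scan_motif(spliced, mode="strict") == []
    truths["euplokamis|bhlhpas"] = type(ct)(
        protein_id=ct.protein_id,
        sequence=spliced,
        domain_intervals=ct.domain_intervals,
        tail_interval=ct.tail_interval,
        planted_positions=ct.planted_positions,
        tail_counts=ct.tail_counts,
    )
    lines = []
    for pid in sorted(truths):
        lines.append(f">{pid}")
        s = truths[pid].sequence
        lines.extend(s[i : i + 60] for i in range(0, len(s), 60))
    fasta = "\n".join(lines) + "\n"
    (OUT / "proteome.fasta").write_text(fasta)
    (OUT / "proteome_domains.tsv").write_text(domain_tsv)
    (OUT / "proteome_truth.json").write_text(
        json.dumps(
            {
                pid: {
                    "tail": t.tail_interval,
                    "planted": list(t.planted_positions),
                }
                for pid, t in truths.items()
            },
            indent=1,
        )
    )

    # --- behavioural experiment: three clonal individuals on the stepped
    # schedule, 30 s cadence, mild area and O2 measurement noise
    (OUT / "traces").mkdir(exist_ok=True)
    truth_summary = {}
    for i in range(3):
        truth = make_experiment_truth(
            SCHEDULE,
            FULL_RATES,
            sub_rates_per_day=SUB_RATES,
            seed=SEED + i,
            noise_sd=60.0,
            o2_noise_sd=0.3,
        )
        area, o2 = simulate_experiment(truth)
        area.to_csv(OUT / "traces" / f"area_sponge{i}.csv", index=False)
        o2.to_csv(OUT / "traces" / f"o2_sponge{i}.csv", index=False)
        truth_summary[f"sponge{i}"] = {
            "events": [
                [ev.onset_s, ev.end_s, round(ev.amplitude, 3), ev.klass]
                for ev in truth.events
            ]
        }
    (OUT / "traces" / "event_truth.json").write_text(
        json.dumps(truth_summary, indent=1)
    )

    n_events = sum(len(v["events"]) for v in truth_summary.values())
    print(f"components simulated : {', '.join(COMPONENTS)}")
    print(f"background families  : {len(background)} "
          f"({len(truth_pairs)} true human-tethya 1:1 pairs)")
    print(f"proteome             : {len(plan.proteins)} proteins, "
          f"2 planted strict degrons")
    print(f"experiments          : 3 individuals, {n_events} true "
          f"contraction events over {sum(d for d,_ in SCHEDULE):.0f} h")
    print(f"outputs under        : {OUT}/")


if __name__ == "__main__":
    main()
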
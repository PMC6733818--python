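"""Drive vs frozen: does satellite clustering separate species?

Simulates four-species satellite libraries under the two evolutionary
regimes, pushes reads through the full pipeline (merge -> repeat screen ->
greedy clustering at 95% identity), and prints the fraction of clusters
containing reads from more than one species.  Under homogenising molecular
drive that fraction is ~0 (species-pure clusters); for a conserved
("frozen") satellite the species intermingle and the fraction is large.
"""

from satconnect import (
    RunConfig,
    SimulationConfig,
    pair_reads,
    run_pipeline_from_records,
    simulate_dataset,
)

for mode in ("drive", "frozen"):
    dataset = simulate_dataset(
        SimulationConfig(mode=mode, seed=11, library_size=10, n_pairs=30)
    )
    pairs = pair_reads(dataset.reads_fwd, dataset.reads_rev)
    library = [
        m for sp in sorted(dataset.libraries)
        for m in dataset.libraries[sp][:2]
    ]
    result = run_pipeline_from_records(
        pairs, library, RunConfig(thresholds=(0.95,))
    )
    report = result.report
    mixing, weighted_h = report.mixing_per_threshold[0.95]
    print(
        f"{mode:7s}: {report.input_pairs} pairs -> {report.merged} merged "
        f"-> {report.retained} repeat reads -> "
        f"{report.clusters_per_threshold[0.95]} clusters at 95% identity; "
        f"multi-species cluster fraction {mixing:.2f}, "
        f"composition entropy {weighted_h:.2f} nats"
    )

print(
    "\nA fraction near 0 means every cluster is species-specific (the"
    "\nmolecular-drive expectation); a large fraction means satellite"
    "\nvariants are shared across species (a conserved satellite)."
)
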
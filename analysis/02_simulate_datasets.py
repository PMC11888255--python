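#!/usr/bin/env python
"""Generate one ground-truthed synthetic dataset per modality.

Outputs land under results/synthetic/: calcium traces + truth spikes, spine
trajectories for both conditions + tercile truth, an mEPSC current trace +
event truth, and a c-Fos stack + blob truth.  Every later driver re-reads
these or regenerates with the same seeds.
"""

from pathlib import Path

from tbslice import io
from tbslice.synthetic_data import (CalciumSimParams, CfosImageParams,
                                    MepscSimParams, SpineSimParams,
                                    simulate_calcium_traceset,
                                    simulate_cfos_stack, simulate_mepsc_trace,
                                    simulate_spine_trajectory_set)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20260930


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ts, spikes = simulate_calcium_traceset(CalciumSimParams(seed=SEED))
    io.write_traces_csv(ts.traces, OUT / "calcium_traces.csv", ts.unit_ids)
    io.dump_json({"spike_times": [list(map(float, s)) for s in spikes]},
                 OUT / "calcium_truth.json")
    print(f"calcium: {ts.n_units} units x {ts.n_frames} frames, "
          f"{sum(len(s) for s in spikes)} true spikes")

    for cond in ("control", "stimulated"):
        sset, truth = simulate_spine_trajectory_set(
            SpineSimParams(seed=SEED + 1), condition=cond)
        sset.sizes.to_csv(OUT / f"spines_{cond}.csv", index=False)
        truth.to_csv(OUT / f"spines_{cond}_truth.csv", index=False)
        print(f"spines ({cond}): {sset.sizes.segment_id.nunique()} segments")

    p = MepscSimParams(seed=SEED + 2)
    trace, etruth = simulate_mepsc_trace(p)
    io.write_trace_table(trace, p.sampling_rate, OUT / "mepsc_trace.csv")
    etruth.to_csv(OUT / "mepsc_truth.csv", index=False)
    print(f"mepsc: {len(etruth)} true events in {p.duration:.0f} s")

    cp = CfosImageParams(seed=SEED + 3)
    cfos, dapi, ctruth = simulate_cfos_stack(cp)
    io.write_stack_tiff(cfos, OUT / "cfos_stack.tif")
    ctruth["blobs"].to_csv(OUT / "cfos_truth_blobs.csv", index=False)
    print(f"cfos: {cp.n_cells} cells, {ctruth['n_qualifying']} qualify "
          f"under default filters")


if __name__ == "__main__":
    main()
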
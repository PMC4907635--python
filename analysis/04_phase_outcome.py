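#!/usr/bin/env python
"""Pre-stimulus alpha phase and the perceptual outcome.

At the cluster electrodes from stage 03: split asynchronous trials by
response, subsample to equal counts, compute first/second-order circular
means per time sample (-200 ms to onset), test phase separation with
Moore's paired R' under cluster permutation over time, and build the
onset-phase bisection used by the proportion analyses.

Writes results/04_phase_outcome.json.
"""

import json
import math
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from alphaphase import pipeline  # noqa: E402


def main():
    common.ensure_dirs()
    feats = common.load_features()
    cluster = json.loads(
        (common.RESULTS / "03_amplitude_cluster.json").read_text()
    )["cluster_electrodes"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pipeline.run_phase_outcome(feats, common.STUDY, tuple(cluster))

    cr = res["cluster_result"]
    best = cr.clusters[0] if cr.clusters else None
    fs = common.STUDY.sim.fs
    out = {
        "cluster_electrodes": cluster,
        "mc_p": cr.mc_p,
        "onset_moore_Rprime": res["onset_moore"].statistic,
        "onset_moore_p": res["onset_moore"].p,
        "preferred_phase_deg": math.degrees(res["preferred_phase"]) % 360,
        "onset_mean_async_deg":
            math.degrees(res["onset_mean_async"].angle) % 360,
        "onset_mean_simul_deg":
            math.degrees(res["onset_mean_simul"].angle) % 360,
        "bisection_boundaries_deg":
            [math.degrees(b) % 360 for b in res["binning"].boundaries],
        "clusters": cr.to_dict()["clusters"],
    }
    if best is not None:
        t0 = (best.members[0] - 100) / fs * 1000
        t1 = (best.members[-1] - 100) / fs * 1000
        out["best_cluster_span_ms"] = [t0, t1]
    (common.RESULTS / "04_phase_outcome.json").write_text(
        json.dumps(out, indent=2, default=float))

    if best is not None:
        print(f"phase cluster {out['best_cluster_span_ms'][0]:.0f} ms to "
              f"{out['best_cluster_span_ms'][1]:.0f} ms relative to onset "
              f"(Monte Carlo p = {best.p:.4f})")
    else:
        print(f"no supra-threshold phase cluster (mc_p = {cr.mc_p:.3f})")
    print(f"onset means: asynchronous {out['onset_mean_async_deg']:.0f} deg, "
          f"simultaneous {out['onset_mean_simul_deg']:.0f} deg; "
          f"R'{res['onset_moore'].n - 1} = "
          f"{res['onset_moore'].statistic:.3f}, "
          f"p = {res['onset_moore'].p:.4f}")
    print(f"preferred phase estimate {out['preferred_phase_deg']:.0f} deg "
          f"(270 deg = alpha trough)")


if __name__ == "__main__":
    main()
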
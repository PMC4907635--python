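#!/usr/bin/env python
"""Attentional modulation of pre-stimulus alpha amplitude.

Cluster-based permutation test over the 24 lateral electrodes (attended =
cue contralateral to the electrode), followed by the per-hemisphere 5 x 2
repeated-measures ANOVAs on the cluster sites and their right-hemisphere
homotopes.  Writes results/03_amplitude_cluster.json.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from alphaphase import pipeline  # noqa: E402


def main():
    common.ensure_dirs()
    feats = common.load_features()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pipeline.run_attention_amplitude(feats, common.STUDY)

    cr = res["cluster_result"]
    out = {
        "cluster_electrodes": list(res["cluster_electrodes"]),
        "cluster_mc_p": cr.mc_p,
        "attended_mean_uv": res["attended_mean"],
        "unattended_mean_uv": res["unattended_mean"],
        "clusters": cr.to_dict()["clusters"],
        "hemisphere_anovas": {
            hemi: {name: res["hemisphere_anovas"][hemi][name].__dict__
                   for name in ("A", "B", "AxB")}
            for hemi in ("left", "right")},
    }
    (common.RESULTS / "03_amplitude_cluster.json").write_text(
        json.dumps(out, indent=2, default=float))

    print(f"suppression cluster: {out['cluster_electrodes']} "
          f"(Monte Carlo p = {cr.mc_p:.4f})")
    print(f"alpha amplitude attended {res['attended_mean']:.2f} uV vs "
          f"unattended {res['unattended_mean']:.2f} uV")
    for hemi in ("left", "right"):
        eff = res["hemisphere_anovas"][hemi]["B"]
        print(f"{hemi} hemisphere attention effect: "
              f"F({eff.df1:.0f},{eff.df2:.0f}) = {eff.F:.3f}, "
              f"p = {eff.p:.4f}, partial-eta2 = {eff.partial_eta_sq:.3f}")


if __name__ == "__main__":
    main()
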
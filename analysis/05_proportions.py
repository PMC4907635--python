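#!/usr/bin/env python
"""Proportion of correctly perceived asynchronous trials by phase bin,
attention and alpha amplitude; polarity paired t-tests.

2x2 repeated-measures ANOVAs (phase bin x attention; phase bin x amplitude
median split) on contralateral-target trials at the cluster electrodes,
plus the polarity (negative vs positive half-cycle) t-tests at the IAF and
with a fixed 10 Hz filter.  Writes results/05_proportions.json.
"""

import json
import math
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from alphaphase import circstats, pipeline  # noqa: E402
from alphaphase.circstats import CircMean  # noqa: E402


def main():
    common.ensure_dirs()
    feats = common.load_features()
    phase_res = json.loads(
        (common.RESULTS / "04_phase_outcome.json").read_text())
    cluster = tuple(phase_res["cluster_electrodes"])
    binning = circstats.make_bisection(
        CircMean(math.radians(phase_res["onset_mean_async_deg"]), 1.0, 20),
        CircMean(math.radians(phase_res["onset_mean_simul_deg"]), 1.0, 20))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pipeline.run_proportion_analyses(feats, common.STUDY, binning,
                                               cluster)

    out = {
        "proportion_async_bin": res["proportion_async_bin"],
        "proportion_simul_bin": res["proportion_simul_bin"],
        "within_subject_se": list(res["within_subject_se"]),
        "anova_phase_attention": {
            k: res["anova_phase_attention"][k].__dict__
            for k in ("A", "B", "AxB")},
        "anova_phase_amplitude": {
            k: res["anova_phase_amplitude"][k].__dict__
            for k in ("A", "B", "AxB")},
        "polarity_t_iaf": res["polarity_t_iaf"].__dict__,
        "polarity_t_10hz": res["polarity_t_fixed"].__dict__,
        "excluded_participants": res["excluded"],
    }
    (common.RESULTS / "05_proportions.json").write_text(
        json.dumps(out, indent=2, default=float))

    a = res["anova_phase_attention"]
    print(f"P(correct | async-defined bin) = "
          f"{res['proportion_async_bin']:.3f} vs "
          f"{res['proportion_simul_bin']:.3f} in the other bin")
    print(f"phase main effect: F(1,{a['A'].df2:.0f}) = {a['A'].F:.3f}, "
          f"p = {a['A'].p:.4f}, partial-eta2 = {a['A'].partial_eta_sq:.3f}")
    print(f"attention main effect: p = {a['B'].p:.3f}; "
          f"interaction: p = {a['AxB'].p:.3f}")
    m = res["anova_phase_amplitude"]
    print(f"amplitude main effect: p = {m['B'].p:.3f}; "
          f"phase x amplitude interaction: p = {m['AxB'].p:.3f}")
    pol = res["polarity_t_iaf"]
    print(f"polarity (negative vs positive half-cycle): "
          f"t({pol.df}) = {pol.t:.3f}, p = {pol.p:.4f}; "
          f"negative {pol.mean_a:.3f} vs positive {pol.mean_b:.3f}")


if __name__ == "__main__":
    main()
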
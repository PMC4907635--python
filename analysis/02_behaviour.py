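#!/usr/bin/env python
"""Behavioural analysis: staircase performance, signal detection, and the
cue-validity effects on RT and SOA threshold.

Writes results/02_behaviour_summary.csv (per participant) and
results/02_behaviour_tests.json (group tests).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from alphaphase import behaviour  # noqa: E402


def main():
    common.ensure_dirs()
    feats = common.load_features()
    summary = behaviour.behavioural_summary([f.trials for f in feats])
    summary.to_csv(common.RESULTS / "02_behaviour_summary.csv", index=False)

    rt = behaviour.paired_t(summary["rt_valid"], summary["rt_invalid"])
    soa = behaviour.paired_t(summary["soa_valid"], summary["soa_invalid"])
    hit = behaviour.paired_t(summary["hit_rate_valid"],
                             summary["hit_rate_invalid"])
    out = {
        "hit_rate_mean": summary["hit_rate"].mean(),
        "hit_rate_sd": summary["hit_rate"].std(ddof=1),
        "fa_rate_mean": summary["fa_rate"].mean(),
        "d_prime_mean": summary["d_prime"].mean(),
        "d_prime_sd": summary["d_prime"].std(ddof=1),
        "soa_mean_ms": summary[["soa_valid", "soa_invalid"]].mean().mean(),
        "rt_valid_ms": summary["rt_valid"].mean(),
        "rt_invalid_ms": summary["rt_invalid"].mean(),
        "rt_test": rt.__dict__,
        "soa_test": soa.__dict__,
        "hit_rate_test": hit.__dict__,
    }
    (common.RESULTS / "02_behaviour_tests.json").write_text(
        json.dumps(out, indent=2, default=float))

    print(f"hit rate {out['hit_rate_mean']:.3f} (SD "
          f"{out['hit_rate_sd']:.3f}); FA {out['fa_rate_mean']:.3f}; "
          f"d' {out['d_prime_mean']:.3f}")
    print(f"SOA {out['soa_mean_ms']:.0f} ms; RT valid "
          f"{out['rt_valid_ms']:.0f} vs invalid {out['rt_invalid_ms']:.0f} ms "
          f"(t({rt.df}) = {rt.t:.2f}, p = {rt.p:.2e}, g_av = {rt.g_av:.2f})")


if __name__ == "__main__":
    main()
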
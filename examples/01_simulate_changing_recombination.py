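"""Simulate a locus whose recombination rate declined logistically.

Builds a logistic rate trajectory (rate low at present, high 10^4
generations ago, same total recombination as a constant-rate locus),
simulates a 100-haplotype sample of a 10-kb locus, and prints the summary
statistics next to a constant-rate control.
"""

from recombpast import (SimulationConfig, preset_profile, simulate, summarize,
                        write_ms)

for name in ("constant", "logistic-dec"):
    cfg = SimulationConfig(profile=preset_profile(name), seed=1)
    ds = simulate(cfg)
    sv = summarize(ds)
    print(f"{name:>13}: S={sv.S:.0f} Rmin={sv.Rmin:.0f} nHaps={sv.nHaps:.0f} "
          f"HapDiv={sv.HapDiv:.3f} HudsonC={sv.HudsonC:.2f} ZnS={sv.ZnS:.3f}")
    write_ms([ds], f"{name}.ms")

print("\nBoth loci carry the same *total* recombination; the declining locus")
print("apportions it to the deep past, which shifts the LD-based summaries")
print("(Hudson's C, ZnS) even though the mean number of segregating sites S")
print("is the same in expectation.  Each sample was also written in")
print("ms format next to this script.")
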
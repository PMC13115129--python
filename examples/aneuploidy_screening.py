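"""Call whole-chromosome aneuploidies from a binned read-depth track.

Simulates an embryo genome with a trisomy and a monosomy, estimates per-bin
copy number as 2 x depth / median depth, and applies the CN > 2.6 (trisomy)
and CN < 1.4 (monosomy) thresholds per chromosome.
"""

from egscreen import (
    CNEvent,
    call_aneuploidy,
    depth_cv,
    estimate_copy_number,
    simulate_depth_track,
)

genome = {str(c): 100_000_000 for c in range(1, 6)}
events = [
    CNEvent(chrom="2", copy_number=3, whole_chromosome=True),
    CNEvent(chrom="4", copy_number=1, whole_chromosome=True),
]
track = simulate_depth_track(genome, bin_size=1_000_000, depth_mean=10,
                             depth_dispersion=1.5, cn_events=events, seed=21)

profile = call_aneuploidy(estimate_copy_number(track))
print(f"genome median depth: {profile.genome_median_depth:.1f}x")
for c in profile.per_chromosome:
    print(f"chr{c.chrom}: median CN {c.summary_cn:.2f} -> {c.call} "
          f"({c.fraction_bins_abnormal:.0%} of bins abnormal)")
# chr2 should read near CN 3 (trisomy), chr4 near CN 1 (monosomy), the rest
# near CN 2.

curve = depth_cv(track, (1_000_000, 10_000_000, 100_000_000))
print("\namplification-bias curve (CV of depth per window):")
for w in curve.window_sizes:
    print(f"  {w/1e6:>6.0f} Mb windows: CV = {curve.cv_per_window[w]:.3f}")
# CV shrinks as windows grow; a heavily biased amplification would keep CV
# high even at large windows.
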
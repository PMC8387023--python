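# replirate

Quantification of replisome kinetics from two assay read-outs:

1. **CMG helicase unwinding rate** from a restriction-protection qPCR assay.
   A linear template carries an origin at one end and cassettes of four
   tandem MseI sites (TTAA) at 200, 500, 1000, 1500 and 2000 bp from the
   origin. MseI cuts double-stranded DNA only, so once the helicase has
   unwound past a cassette the amplicon spanning it survives digestion and
   amplifies. The unwound fraction at site *d* and time *t* is estimated as

       f̂_d(t) = [mean quantity(d, t) / mean control(t)] / plateau(ref)

   (triplicate wells averaged; control amplicon cancels the per-sample
   loading factor; the closest site's fitted saturation level defines 1).
   Each site's time course gets a monotone shape-preserving spline; the mean
   arrival time is τ_d = ∫₀ᵀ (1 − f̂_d(t)) dt, the site rate is d/τ_d, and
   the reported rate is the mean over the three distal sites, with a
   cell-wise bootstrap 95% CI.

2. **Replication fork rate** from nascent leading-strand smears on alkaline
   (denaturing) agarose gels. Lane profiles are decoded to linear intensity,
   migration is calibrated as bp(x) = a·e^(−bx) from a ladder, lanes are
   smoothed, the leading fork length is the high-molecular-weight position
   where the signal first reaches 20% of the lane maximum, and the fork rate
   is the OLS slope of length vs. time (kb/min). The same caller handles
   BrdU pulse-chase lanes, where the percent slowdown between strains is
   100·(r_ref − r_alt)/r_ref.

The package also ships seeded stochastic generators for both read-outs
(two-state pausing motor with asynchronous activation; label-weighted gel
smears with exponential migration) so every pipeline can be validated by
round-trip parameter recovery, plus the assay template sequence and primer
table as packaged fixtures.

Intended users: people building or quantifying in vitro replication
(helicase/replisome reconstitution) assays, and anyone needing a tested
reference implementation of restriction-protection qPCR or gel-densitometry
rate estimation.

## Worked example

```python
import replirate as rr
from replirate.data import pawm36_fasta_path, assay_primers_path

# 1. check the assay design: amplicons and their MseI content
template = rr.read_fasta(pawm36_fasta_path())
assay = rr.map_assay(template, rr.read_primer_table(assay_primers_path()))
for label, amp in assay.amplicons.items():
    print(f"{label:>8}  [{amp.start:4d}, {amp.end:4d})  {amp.length:3d} bp  "
          f"TTAA x{amp.motif_count}  control={amp.is_control}")

# 2. simulate a triplicate qPCR plate at 79 bp/min net velocity and analyze it
params = rr.UnwindingParams.from_net_velocity(79.0, n_molecules=2000, seed=1)
plate = rr.simulate_qpcr_readout(rr.simulate_unwinding(params),
                                 rr.QpcrNoiseModel(), seed=1)
est = rr.bootstrap_rate_ci(plate, B=1000, seed=1)
print(f"rate = {est.rate:.1f} bp/min, 95% CI ({est.ci[0]:.1f}, {est.ci[1]:.1f})")

# 3. simulate gel lanes at 0.7 kb/min and recover the fork rate
lane_set = rr.simulate_gel_lanes(rr.GelSimParams(fork_rate=0.7, seed=1))
res = rr.analyze_lane_set(lane_set)
print(f"fork rate = {res.fit.slope:.3f} kb/min (r^2 = {res.fit.r_squared:.4f})")
```

Output:

```
     200  [1152, 1245)   93 bp  TTAA x4  control=False
     500  [1362, 1543)  181 bp  TTAA x4  control=False
    1000  [1877, 2076)  199 bp  TTAA x4  control=False
    1500  [2413, 2518)  105 bp  TTAA x4  control=False
    2000  [2909, 3084)  175 bp  TTAA x4  control=False
 control  [3066, 3220)  154 bp  TTAA x0  control=True
rate = 78.4 bp/min, 95% CI (71.2, 79.8)
fork rate = 0.720 kb/min (r^2 = 1.0000)
```

The amplicon table confirms the template design: five primer pairs flank
cassettes of exactly four TTAA motifs and one control pair flanks none. The
unwinding estimate recovers the generative 79 bp/min to within a few
percent (the small deficit is the documented activation-delay bias), and
the densitometry chain recovers the generative fork rate to ~3%.

The same workflows are available from the `replirate` console script
(`map-template`, `simulate-unwinding`, `analyze-unwinding`, `simulate-gel`,
`analyze-gel`, `simulate-pulse-chase`, `analyze-pulse-chase`); run
`replirate --help` for the subcommand reference.

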
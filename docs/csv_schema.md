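# CSV output schemas

All CSVs are written by `structdrift.io`; columns appear in the order below.

## trajectory_XXXX.csv (`drift` subcommand; `io.write_trajectory_csv`)

One row per recorded generation of one realization.

| column | meaning |
| --- | --- |
| realization | realization index within the ensemble |
| generation | generation index t (0 = initial machine) |
| h_mu | allelic entropy of the generation's machine, bits/allele |
| C_mu | allelic complexity, bits |
| pr_symbol | stationary probability of the tracked allele `'1'` (NaN when the machine was not retained under the chosen history level) |
| signature | isostructural-subspace label of the machine topology |
| event | how this machine arose: `none`, `innovation_accepted`, `loss_merge`, `subspace_jump` |

## ensemble_summary.csv (`io.write_ensemble_summary`)

One row per realization: `realization, generations, terminal_status,
terminal_signature, terminal_h_mu, terminal_C_mu`.

## ce_points.csv (`analyze`; `io.write_ce_points`)

Complexity-entropy diagram points, one row per generation per realization:
`realization, generation, h_mu, C_mu, signature`.

## pathways.csv (`analyze`)

One row per pathway (ordered sequence of subspaces traversed to stasis):
`pathway, n, weight, mean_time, se`.  `weight` is the empirical pathway
probability; weights sum to 1 over the absorbed ensemble.

## dwell_times.csv (`analyze`)

One row per (pathway, subspace position): `pathway, position, signature,
n, mean_dwell, se`.  Dwell counts generations from subspace entry
(inclusive) to exit (exclusive); per pathway, mean dwells sum exactly to
the pathway's mean stasis time.

## entry_params.csv (`analyze`)

Transition probabilities of the branching states at each subspace entry:
`pathway, position, signature, member, state, symbol, p`.

## kimura CSV (`kimura` subcommand)

`p0, mean_t_fix, se, n_fixed, n_realizations, theory_t1, theory_t0` —
fixation-conditioned Monte Carlo means against the diffusion-theory
conditional absorption times.

## Machine JSON

`{"alphabet": [...], "states": [...], "transitions": [{"from", "symbol",
"to", "p"}, ...], "notes": "..."}` with sorted keys; round-trips exactly.
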
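# infolearn

Model-based information dynamics of reward and punishment learning in
trial-locked neural power signals.

During probabilistic instrumental learning, outcome-locked gamma-band
(50–100 Hz) activity in prefrontal and insular cortex tracks reinforcement
prediction errors.  Whether different regions carry *overlapping* or
*complementary* information about reward prediction errors (RPE) and
punishment prediction errors (PPE) — and in which direction that information
flows — is a network-level question that pairwise correlations cannot
answer.  `infolearn` is a reusable pipeline for exactly this analysis:

1. **Behavior model.** A Q-learning agent with delta-rule updates
   `Q ← Q + α·δ`, `δ = R − Q`, softmax choice with temperature β and a
   perseveration bonus θ for the previously chosen cue.  Parameters are fit
   per subject by multistart maximum likelihood; trial-wise prediction
   errors δₜ are split into RPE (reward pairs, outcomes +1€/0€) and PPE
   (punishment pairs, −1€/0€).
2. **Spectral stage.** Bipolar referencing, sliding multitaper gamma power
   (9 Slepian tapers, 200 ms windows centred at 75 Hz), 256 Hz downsampling
   and Savitzky–Golay smoothing turn raw trial-locked voltage into
   single-trial power epochs.
3. **Information estimators** (Gaussian-copula, bias-corrected, in bits),
   computed across trials at every time sample:
   * mutual information `MI = I(γ; PE)` per contact;
   * interaction information
     `II(γ₁, γ₂; PE) = I(γ₁,γ₂; PE) − I(γ₁; PE) − I(γ₂; PE)`,
     negative when the pair encodes the PE redundantly, positive when
     synergistically;
   * transfer entropy `TE(X→Y) = I(X_{t−d}; Y_t | Y_{t−d})` averaged over a
     116–236 ms delay window, estimated separately on reward and punishment
     trials.
4. **Group statistics.** Random-effects one-sample t-tests against each
   unit's own permutation mean, cluster-mass correction against the largest
   permuted cluster masses, per-contact selectivity categorization
   (RPE / PPE / Both / Irrelevant), selectivity-binned II with
   Benjamini–Hochberg FDR, paired condition contrasts, and inter-subject
   reproducibility summaries.

Because real intracranial recordings are not shippable, the package includes
a first-class synthetic-data module that reproduces the task (4 cue pairs ×
24 repetitions per session, reciprocal 0.75/0.25 contingencies), simulates
the agent, and builds outcome-locked power epochs with *known* redundant,
synergistic and lagged-directed structure — so every estimator is exercised
end-to-end against ground truth.

## Worked example

```bash
infolearn simulate --seed 3 --out runs/demo
infolearn fit      --seed 3 --out runs/demo
infolearn analyze  --seed 3 --n-perm 100 --out runs/demo
infolearn report   --seed 3 --n-perm 100 --out runs/demo
cat runs/demo/report.md
```

With the default cohort (8 contacts per subject, couplings at 500 ms
latency) an 8-subject run prints:

```
- **ii_rpe** (redundant (II < 0)): 3 significant cluster(s); 0.010 over 0.395-0.426 s; ...
- **ii_ppe** (redundant (II < 0)): 2 significant cluster(s); 0.010 over 0.348-0.598 s; ...
- **ii_syn** (synergistic (II > 0)): 1 significant cluster(s); 0.010 over 0.285-0.723 s
- **TE aINS->dlPFC**: 1 cluster(s) with TE_Pun > TE_Rew; 0 reversed

## II by selectivity category
category  n_pairs     mean        t  dof        p    p_fdr
 PPE-RPE        7 0.003495 3.496704    6 0.012878 0.012878
   Mixed        9 0.143631 7.373144    8 0.000078 0.000156
```

Reading this: the vmPFC–lOFC pairs carry redundant (negative II) RPE-specific
information and the aINS–dlPFC pairs redundant PPE-specific information, both
clustering around the 500 ms response latency they were generated with; the
punishment-gated aINS→dlPFC drive appears as a TE_Pun > TE_Rew cluster with no
reversed cluster; and the pairs spanning the two subsystems show net
*synergy* (positive II) about the full signed prediction error, significant
after FDR in the PPE-RPE and Mixed selectivity categories.

The same objects are available as a library (`infolearn.synth`,
`infolearn.dynamics`, `infolearn.stats`, `infolearn.pipeline.run`), with all
intermediate results saved as CSV/JSON/HDF5 plus a checksummed manifest.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the task-design constant that is checkable at desk scale — the
empirical favourable-outcome frequency of a high-probability cue over
100,000 fresh draws from the task generator — and writes it as JSON.

See `docs/methods.md` for the model details, estimator conventions, default
parameters and known limitations.
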
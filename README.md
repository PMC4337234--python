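# patterngrid

Quantifying the destabilization of maladaptive personality patterns across a
course of cognitive therapy, from observationally coded session content.

## The problem

Personality disorders can be viewed as entrenched attractors of a dynamic
system: self-reinforcing configurations of cognition, emotion, behavior and
somatic functioning.  Effective therapy is then a perturbation that loosens
the pathological (negative) pattern so that a more adaptive (positive)
pattern can form and stabilize.  `patterngrid` implements the measurement
chain that makes this idea quantitative when therapy sessions are rated with
the CHANGE observational coding system (ordinal 0–3 ratings by two
independent coders):

1. **Coder averaging.** Two coders' ratings per session are averaged item by
   item.
2. **Node scores.** Per valence, a *cognitive* node is the mean of View of
   Self, Hope and Relationships; the Emotion, Behavior and Somatic ratings
   are taken directly.
3. **Pattern strength** `S = cog + emo + beh + som ∈ [0, 12]` — overall
   intensity, used at baseline (session 1) and posttreatment (the coded
   session closest to session 34).
4. **Pattern activation** `A = #{nodes ≥ 2} ∈ {0..4}` — multimodal breadth.
   Each session becomes a point (positive activation, negative activation)
   on a 5×5 state-space grid.
5. **Dispersion** per treatment phase (phase 1: sessions 1–10, baseline
   excluded; phase 2: sessions 11–34, posttreatment excluded):

   `disp = 1 − [ n Σᵢ (dᵢ/D)² − 1 ] / (n − 1)`

   with `dᵢ` the sessions in grid cell *i*, `D` the coded sessions in the
   phase, and `n = 25` the total cell count — 0 when every session occupies
   one cell, 1.00 when sessions spread evenly over the whole grid.
6. **Outcome statistics.** Pairwise Pearson intercorrelations, paired
   t-tests with Cohen's *d* (= mean diff / SD of differences), and
   hierarchical OLS regressions predicting posttreatment outcome from the
   pretreatment score (step 1) plus phase dispersion and peak emotional
   processing (step 2), with ΔR² and its F test.  A bridge routine also
   reconstructs standardized regressions directly from a printed
   correlation matrix (β = Rxx⁻¹ rxy).

Because session recordings of this kind are not publicly shareable, the
package ships a synthetic-cohort generator (`patterngrid.synthetic`): a
two-state Markov chain per patient flickers between a negative-dominant and
a positive-dominant attractor, sessions emit ordinal ratings for two noisy
coders, and outcomes follow a planted linear model on the *measured*
dispersion and processing — so the entire pipeline is testable, including
end-to-end parameter recovery.

## Worked example

```bash
patterngrid analyze --simulate --seed 7 --out demo
```

generates a 27-patient synthetic cohort, validates it, and writes the full
report bundle (`summaries.csv`, `table1_correlations.csv`,
`paired_tests.csv`, `regressions_phase1.csv`, `regressions_phase2.csv`,
GridWare-style trajectory files, and a run log with the config hash).
Excerpts from that run:

```text
# paired_tests.csv (rounded)
contrast                           mean_diff  sd_diff      t      p  cohen_d
negative_strength_pre_minus_post       3.469    2.425  7.434  0.000    1.431
processing_phase1_minus_phase2        -0.593    0.721 -4.270  0.000   -0.822

# regressions_phase2.csv, outcome = positive pattern strength at post
step  term               B       beta    t      p      R2     dR2    dF     p_dF
1     (step)                                           0.001  0.001  0.016  0.901
1     pos_strength_pre   0.078   0.025   0.126  0.901
2     (step)                                           0.469  0.468 10.133  0.001
2     pos_strength_pre   0.976   0.313   1.881  0.073
2     dispersion2       11.842   0.575   3.588  0.002
2     peak_processing2   1.565   0.358   2.189  0.039
```

Reading: negative pattern strength drops from baseline to posttreatment
(mean difference 3.47 strength points, *d* = 1.43), and adding phase-2
dispersion and peak processing to the pretreatment score raises R² from
0.001 to 0.47 (ΔF = 10.1, p = .001) — at this small *n* the step-2
estimates are noisy, but both process variables carry the planted positive
coupling to outcome.  The same commands work on real coded data via
`--codings`/`--outcomes` (long CSV, one row per patient–session–coder; see
`patterngrid.coding_io`).

Scalar building blocks are available directly:

```python
>>> from patterngrid import NodeScores, pattern_strength, activation_score
>>> nodes = NodeScores("neg", cognitive=3, emotion=3, behavior=3, somatic=1)
>>> pattern_strength(nodes), activation_score(nodes)
(10.0, 3)
```

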
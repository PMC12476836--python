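# Methods

## Problem and model

A SLiM screen asks: given a bait protein and a list of candidate partners,
which candidates carry a short linear motif that binds the bait?  Each
candidate is modelled as a binary complex with the bait by AlphaFold; the
package then works entirely on the prediction's confidence outputs.

The central statistic is **MiniPAE**: the minimum of the predicted aligned
error matrix over all residue pairs spanning the two chains, taking both
off-diagonal blocks of the (asymmetric) matrix.  A genuine motif interface
produces a localized stripe of low inter-chain PAE, so MiniPAE is low for
binders and stays near the background for non-binders.  The per-residue
minimum inter-chain PAE (the row/column-wise minimum for each candidate
residue) localizes the motif: the call is anchored at the arg-min (first
occurrence on ties) and extended to the maximal contiguous run of residues
within `delta` (default 3.0 Å) of the minimum.  One call per prediction is
the default, because MiniPAE is defined by a single global minimum;
`all_islands=True` reports every within-band island.  The 3 Å band is the
package's own window rule: it recovers a planted stripe exactly whenever
the background exceeds the stripe by more than `delta`, and it yields a
single contiguous motif per prediction, consistent with screens reporting
roughly one motif per accepted candidate.

Supporting metrics: **Model Confidence** `MC = 0.2·pTM + 0.8·ipTM`, and
**AlphaSLiM** `N·(pLDDT_bound − pLDDT_unbound)` per residue, which isolates
disorder-to-order transitions on binding from constitutively structured
regions (plain pLDDT is high in both).  `N` is evaluated per residue — the
per-residue profile definition requires it — as the number of bait heavy
atoms within a cutoff (default 4.0 Å) of any heavy atom of that residue.
This geometric contact count is a deterministic proxy for interaction-
profiler output; externally computed counts can be substituted by
constructing `ContactCounts` directly.  AlphaSLiM motif calls are maximal
runs of strictly positive values, scored by the run maximum.

## Adaptive threshold

A fixed MiniPAE cutoff cannot serve screens of different sizes: the minimum
score among `n` non-binders is an extreme-value statistic that decreases
with `n`.  The calibration procedure estimates the curve
`E[min of n non-binder MiniPAEs]` by subsampling: for each size `n`, draw
`n` scores from the non-binder pool without replacement (subsampling a
dataset implies subsets; `with_replacement=True` is available), record the
minimum, repeat 100 times, and average.  The curve is summarized by the
three-parameter power law `y = a·x^(−b) + c`, fitted with
`scipy.optimize.curve_fit` (Levenberg–Marquardt, start values
`a = range(y)`, `b = 0.3`, `c = min(y)`, which make minima-shaped curves
converge robustly).  An exactly flat curve short-circuits to the degenerate
solution `a = 0, c = mean(y)` since the Jacobian in `b` vanishes there.
The fitted `predict(n)` is the screen-size-dependent cutoff; with the
published constants `(30.29, 0.2803, −3.82)` it gives 2.859 Å at `n = 220`
(applied in practice as 2.85).  Filtering is inclusive (`score ≤
threshold` passes): the published usage does not state strictness, and the
inclusive choice is conservative for recall.  The fit reports only
per-point standard deviations and the residual sum of squares; no further
uncertainty quantification is attempted.

Default size grid `{1, 2, 5, 10, 25, 50, 100, 250, 500, 1000}` (capped at
the pool size): log-spaced coverage of realistic screening scales.  One
integer seed controls the whole procedure; each size gets its own stream
spawned deterministically from it (`numpy.random.SeedSequence.spawn`), so
extending the grid never perturbs existing points.

## Benchmark evaluation

ROC AUC is the rank statistic (ties half-credit), computed via
scikit-learn; PR-AUC is trapezoidal integration of precision over recall,
on the curve from `sklearn.precision_recall_curve` including the
conventional (recall 0, precision 1) anchor.  The ratio-subsampled PR
analysis draws `ratio × n_pos` negatives without replacement per iteration
(default 10 iterations) and averages AUCs; curves are averaged after
linear interpolation of precision onto a fixed 101-point recall grid,
since per-draw curves have incommensurate support.  TPR at FDR = 0 counts
positives *strictly* better than the best negative: a tie already
constitutes a false discovery at that threshold.  Orientation
(lower-is-better vs higher) is an explicit argument everywhere and never
inferred from data — silent inference is the classic source of inverted
AUCs.

Shuffled negatives re-pair motifs with partners they are not annotated to
bind, excluding (i) annotated positive pairs, (ii) pairs where the motif
sequence matches any regex associated with the new partner (patterns of
motifs known to bind it; unanchored `re.search`, matching ELM semantics) —
these could be functional by accident — and (iii) pairs whose combined
length reaches 1000 residues (prediction-cost cap).  Draws are uniform
without replacement from the full admissible set.

## File dialects

ColabFold score JSON carries no chain boundaries, so the reader requires
explicit `chain_lengths` or the companion structure file.  When several
ranked models exist, rank 1 is scored by default (the community default;
`--rank` overrides) with the rank parsed from the `rank_NNN` filename
token.  AF3-server bundles (directory or zip) are reduced to residue
level: atom pLDDTs are averaged per residue; token-level PAE is mapped by
taking the minimum over a residue pair's token pairs — the identity for
standard one-token-per-residue proteins, conservative toward detecting
contacts otherwise.  Real server bundles do not ship an explicit
atom→residue map; the reader honours optional `atom_res_ids` /
`token_res_ids` arrays when present and otherwise assigns one entry per
residue sequentially per chain.  PAE matrices are kept asymmetric as
emitted (MiniPAE minimizes over both blocks anyway).  pLDDT uses the 0–100
convention throughout.  Motif coordinates are 1-based inclusive within the
candidate chain; the internal concatenated axis is 0-based.

## Synthetic fixtures

The generator emulates the *statistical signature* of SLiM predictions: a
rectangular low-PAE stripe (motif residues × bait, both orientations) at
`stripe_pae` against a `background_pae` field, optional i.i.d. Gaussian
noise clipped to AlphaFold's practical PAE range [0.2, 31.75] Å, a pLDDT
boost on motif residues, and a CA-only PDB whose motif residues sit 3 Å
from a bait CA (inside the 4 Å contact cutoff) while the rest of the
candidate lies 30 Å away.  Defaults — 120-residue bait, 80-residue
candidate, 8-residue motif, 2 Å stripe vs 25 Å background, pTM 0.6 /
ipTM 0.7 — represent a typical confident SLiM prediction in a screen of
sub-1000-residue proteins.  The monomer ("unbound") pLDDT track reuses the
bound track's base-noise realization, so ΔpLDDT equals the boost exactly
on the motif and zero elsewhere even under noise.

What the fixtures do **not** model: AlphaFold's spatially correlated error
structure, rank-dependent model variability, partial or split interfaces,
and any sequence–structure relationship (chains are alanine/glycine
geometry only).  Passing tests therefore demonstrate that the machinery —
parsing, scoring, localization, thresholding, evaluation — is correct on
in-distribution inputs with known truth; they do not re-establish the
empirical screening performance of AlphaFold on real proteomes, which
requires the original large-scale prediction sets.

## Numerical and design notes

- Ties in any arg-min/arg-max are broken by the first occurrence in index
  order: deterministic and order-stable.
- The inverse normalization `(1/x − inv_min)/inv_max` is implemented
  exactly as defined by its source even though the best score does not map
  to 1 (the denominator is `inv_max`, not `inv_max − inv_min`); fidelity
  over cosmetic correction, flagged prominently in the docstring.
- `filter_calls` re-annotates every call with `passed`; filtering is
  idempotent.
- Degenerate inputs raise typed exceptions (`slimpae.errors`) rather than
  returning sentinel values: empty pools, all-zero normalization input,
  single-chain records, undersized fit curves, exhausted shuffle spaces.
- Problem sizes in the test suite (chains of 60–200 residues, screens of
  24–40 synthetic candidates, 100-draw property sweeps, pools of ~1100
  scores) were chosen so the full suite exercises every code path at
  realistic shapes while remaining quick to run end to end.
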
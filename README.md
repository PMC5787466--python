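# hopscreen

Bottom-up ligand design and reductive-filter virtual screening for
small-molecule inhibitor discovery.

`hopscreen` is for computational and medicinal chemists who have a few
known inhibitors of a target and want new chemotypes without a compound
library or a high-throughput screen.  It was built around the discovery
setting for SCD1 (stearoyl-CoA desaturase 1) inhibitors, where a handful
of commercial inhibitors seeded a campaign of core hopping plus staged
structure-based filtering, but the machinery is target-agnostic.

The pipeline:

1. **Core separation** — each parent inhibitor is split into its central
   scaffold (Murcko framework: ring systems + linkers) and its peripheral
   "edges", cut at exocyclic single bonds.  The decomposition is exactly
   invertible.
2. **Hybrid enumeration** — pooled edges are fused onto a library of
   replacement cores; products are sanitized, deduplicated and screened
   against a structural-alert dictionary, then energy-minimized (MMFF94).
3. **Shape filter** — each candidate's conformer ensemble is overlaid on
   the parents with a first-order Gaussian volume model and scored with
   the shape Tanimoto `T = V_AB / (V_AA + V_BB − V_AB)`.
4. **Docking retention** — externally produced docking scores (kcal/mol)
   are ingested from CSV; the best `ceil(f·N)` candidates are retained and
   the known-inhibitor controls are always added back.
5. **3D-QSAR** — pharmacophore hypotheses (A/D/H/N/P/R features with
   inter-feature distances) are enumerated from the most active training
   compounds; aligned grid occupancies feed a PLS regression of
   pIC50 = 9 − log₁₀(IC50/nM), with leave-one-out component selection, a
   strict <500 nM gate, and a feedback-retraining entry point for new
   assay results.
6. **Composite Z-score** — the three metrics are each normalized to the
   top performer (D_i, S_i, Q_i) and combined as

       Z_sum = D_i + S_i + Q_i        Z_avg = Z_sum / 3

   ranking candidates for synthesis selection, with Lipinski Rule-of-5 /
   Jorgensen Rule-of-3 violation counts reported alongside.

See `docs/methods.md` for the model details, parameter choices and known
limitations.

## Worked example

Score the four lead candidates of a screen from their raw docking scores
(kcal/mol), best shape similarities, and QSAR-predicted IC50s (nM),
against the best performer of each metric:

```python
from hopscreen import composite_zscore, normalize_metric
from hopscreen.zranker import to_table

dock  = {"SSI-1": -9.92,   "SSI-2": -9.0,   "SSI-3": -10.38, "SSI-4": -10.91, "best": -12.55}
shape = {"SSI-1": 0.513,   "SSI-2": 0.881,  "SSI-3": 0.803,  "SSI-4": 0.660,  "best": 0.642}
qsar  = {"SSI-1": 1099.08, "SSI-2": 381.09, "SSI-3": 126.19, "SSI-4": 339.65, "best": 30.98}

records = composite_zscore(
    normalize_metric(dock, "lower_better"),
    normalize_metric(shape, "higher_better"),
    normalize_metric(qsar, "lower_better"),
)
print(to_table(records).to_string(index=False))
```

prints

```
 rank  name  dock_norm  shape_norm  qsar_norm  z_sum  z_avg
    1  best       1.00        0.73       1.00   2.73   0.91
    2 SSI-3       0.83        0.91       0.25   1.98   0.66
    3 SSI-2       0.72        1.00       0.08   1.80   0.60
    4 SSI-4       0.87        0.75       0.09   1.71   0.57
    5 SSI-1       0.79        0.58       0.03   1.40   0.47
```

Each sub-metric is the compound's score relative to the best performer
(1.00 = best docking / shape / predicted potency in the pool); `z_avg` is
the composite used for ranking, so here SSI-3 is the strongest of the
four leads — potent prediction and good shape outweigh SSI-4's better
docking score.

The full funnel runs from a config:

```bash
hopscreen run --config pipeline.yaml --seed 7 --out-dir out/
```

which writes per-stage manifests, the ranked Z-score table joined with
druglikeness columns (`final_report.csv`), and a funnel summary; re-running
from the emitted `resolved_config.yaml` reproduces every output byte.
Individual stages are exposed as `hopscreen enumerate | shape |
dock-filter | druglikeness`.

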
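# delphiframe

Consensus-based criterion frameworks for designing medical devices that stay
usable in low-resource settings are built from expert surveys: an
international panel rates the importance of candidate design criteria
(consumables, spare parts, reliance on power and water, material robustness,
cost, lifetime, ...) on a 5-point Likert scale, and the ratings are distilled
into a ranked, reliability-screened criterion set that can then score real
devices. `delphiframe` implements that entire quantitative chain as a tested,
reusable pipeline for survey methodologists, health-technology-assessment
researchers and device designers:

1. **Delphi consensus** — per criterion, the quartiles of the non-missing
   ratings and their distance Δ = Q3 − Q1 grade consensus: *full* (Δ = 0),
   *fair* (0 < Δ ≤ 1), *sufficient* (1 < Δ ≤ 2), otherwise none. A further
   survey round is required only if some criterion fails to reach consensus;
   new criteria proposed in open answers enter the next round when ≥ 30 % of
   respondents support them.
2. **Ordinal reliability** — per domain, the polychoric correlation matrix
   (two-step maximum likelihood under a latent bivariate normal) feeds the
   standardised Cronbach form α = k·r̄ / (1 + (k − 1)·r̄), i.e. *ordinal
   alpha*, interpreted on the usual bands (≥ 0.9 Excellent ... ≤ 0.5
   Unacceptable). Alpha-if-item-dropped flags items that degrade their scale.
3. **Ranking** — the Relative Index RI = Σ wᵢfᵢ/N with wᵢ = i/5 ranks
   criteria and splits them into Fundamental / Important / Relevant
   subclasses at explicit cutpoints.
4. **Correlation screening** — Goodman–Kruskal γ = (SOP − IOP)/(SOP + IOP)
   over within-domain criterion pairs, flagged *strong* when |γ| > 0.5 and
   p < 0.05.
5. **Framework assembly** — exclusion rules (reliability, midpoint
   importance), a-posteriori criteria, and the discriminatory subset (cost
   and lifetime criteria need a reference device, so they are informative
   only).
6. **Device assessment** — a traffic-light performance matrix (red / yellow
   / green, missing → red by precaution) yields per-criterion trends
   (green in ≥ 5 of 8 devices by default) and per-device efficiency classes
   (modal colour, ties resolved to the worse class).

Because raw expert-panel responses are rarely shareable, the package ships a
latent-trait simulator (`delphiframe.simulate`) that generates panels with
the structure the analysis assumes — correlated Likert blocks per domain,
a plantable negatively keyed item, MCAR "Do not know" cells — so every stage
is testable end to end.

## Worked example

```python
import delphiframe as df

codebook = df.load_default_codebook()          # 7 domains, 28 criteria
table = df.generate_responses(df.study_panel_spec(seed=1))  # 25 x 25 Likert

cons = df.DelphiConsensus().fit(table)
rel = df.OrdinalReliability(codebook).fit(table)
rank = df.RelativeIndexRanker().fit(table)
fw = df.assemble(codebook, reliability=rel, consensus=cons.records_,
                 ranking=rank.ranking_)
```

`cons.table_.head(4)` shows every user-type criterion reaching *fair*
consensus (quartiles 4–5 of the 5-point scale), and
`cons.needs_iteration_` is `False` — no further Delphi round is needed:

```text
            n  median   q1   q3  delta label
criterion
1.1        25     4.0  4.0  5.0    1.0  fair
1.2        25     4.0  4.0  5.0    1.0  fair
1.3        25     5.0  4.0  5.0    1.0  fair
1.4        25     4.0  4.0  5.0    1.0  fair
```

`rel.table_` exposes the planted unreliable item: the user-type domain's
ordinal alpha collapses to 0.42 (Unacceptable) and the alpha-drop diagnostic
flags criterion 1.2, while the uncontaminated domains sit at 0.83–0.96:

```text
domain  label                                n_replies  k  alpha  interpretation  flagged_item
1       User type                                   25  4  0.418  Unacceptable    1.2
2       Health technology management (HTM)          21  6  0.958  Excellent
3       Design                                      25  3  0.897  Good
4       Reliance on external factors                19  5  0.907  Excellent
5       Material                                    25  2  0.830  Good
6       Cost                                        25  3  0.899  Good
7       Lifetime                                    25  2  0.862  Good
```

Assembly then drops 1.2 for reliability, keeps the three a-posteriori
resilience criteria (dust, heat, humidity) unranked, and reports
`fw.n_retained == 27` with 22 discriminatory criteria for this simulated
panel. Applying a published set of exclusion flags instead (one reliability
exclusion, one midpoint-importance exclusion) gives the 26-criterion
framework with 21 discriminatory criteria:

```python
fw = df.assemble(codebook, exclude_reliability=["1.2"],
                 exclude_importance=["4.5"])
fw.n_retained, fw.n_discriminatory   # (26, 21)
```

The same stages are available from the shell:

```bash
delphiframe run --simulate --use-paper-flags --seed 5 --out bundle/
delphiframe assemble --out framework.json
delphiframe assess --matrix devices.csv --framework framework.json --out report/
```

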
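# shiftnet

Social-network analysis of team communication on hospital shifts, built for
the longitudinal sociometric-survey design used in emergency-department
communication research: every person on a study shift receives a roster
survey and reports how often they initiated communication toward each named
colleague, separately for three relations (general problem solving,
medication advice seeking, general socializing), on a 0–10 scale whose top
category "10+" means more than ten times. Repeating the survey on one day
shift and one night shift per week over a 12-week period yields 24
shift-points, each with three directed weighted networks.

`shiftnet` turns those survey files into network statistics and reports:

* **Density** — the percentage of dyads (unordered pairs) with at least one
  communication tie in either direction:
  `100 · |ties| / (n(n−1)/2 − excluded)`. Dyads unobservable in both
  directions (both members nonrespondents) are excluded from the
  denominator rather than counted as absent.
* **Degree centralization** (Freeman) — on the symmetrized binary network,
  `C = 100 · Σᵢ(d_max − dᵢ) / ((n−1)(n−2))`: 0 for regular graphs, 100 for
  a star.
* **In-degree centrality** — per member `j`, the count of distinct senders
  reporting toward `j`, standardized by the number of potential senders;
  the network-level in-degree centralization uses the directed Freeman
  denominator `(n−1)²`. Members with maximal in-degree are "stars";
  members with no ties are isolates.
* **QAP tests** — the Pearson correlation between two relation matrices
  over jointly observed off-diagonal cells, with significance from a
  restricted permutation test that relabels one matrix's nodes (rows and
  columns together), preserving each network's autocorrelational
  structure. Small rosters are enumerated exhaustively (exact p);
  otherwise Monte-Carlo sampling with the conservative add-one estimate.
* **Longitudinal reports** — metrics stratified by week × day/night shift,
  night-minus-day density contrasts, boxplot summaries (median/IQR/range,
  significant count) of QAP panels, and GraphML/DOT sociograms in which
  node size encodes in-degree centrality and edge width encodes
  communication frequency.

Because raw sociometric rosters are rarely shareable, the package includes a
first-class synthetic generator (`shiftnet.synthetic_data`) whose latent
structure — per-person sociability, a shared dyadic factor coupling the
three relations, a night-shift density offset, and per-person nonresponse —
is known and recoverable, so every analysis stage is testable end to end.
See `docs/methods.md` for the model and its assumptions.

## Worked example

The bundled four-person example shift (members A, B, C, D; C reports toward
A, B and D, D reports toward A and B) has five of six dyads tied:

```python
>>> from shiftnet.examples import worked_example_network
>>> from shiftnet import dichotomize_symmetrize, density, degree_centralization
>>> net = worked_example_network()
>>> dyads = dichotomize_symmetrize(net, "medication_advice")
>>> round(density(dyads), 1)
83.3
>>> round(degree_centralization(dyads), 2)
33.33
```

Density 83.3% means five of the six possible dyads communicated;
centralization 33.33% (= 2/6) reflects the mild concentration of ties on C
and D (degrees 3, 3, 2, 2).

A full synthetic study from the shell:

```
shiftnet simulate --out study --seed 11
shiftnet metrics  --in study --out metrics.csv
shiftnet qap      --in study --out qap.csv --n-perm 1000 --seed 11
shiftnet report   --in study --out report --seed 11
shiftnet sociogram --in study --shift-id W08-day --relation medication_advice --out socio
```

`metrics.csv` holds one row per (week, shift, relation) with density,
centralization, in-degree centralization and the role(s) of the highest
in-degree member; `qap.csv` one row per shift-point × relation pair with
the observed correlation, permutation p-values, seed and method.

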
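# mapssn

School-neighbourhood built-environment assessment for active-transport
research: street-network buffer zones, microscale streetscape audit scoring,
macro-scale walkability metrics, and the reliability/concordance statistics
used to validate a condensed (one-side-per-segment) audit protocol.

## Who this is for

Researchers auditing the built environment around schools — the sidewalks,
crossings, destinations and aesthetics that shape whether adolescents walk
or cycle to school. In-person streetscape audits are slow; this package
implements the full computational side of a school-neighbourhood audit
workflow so that field effort goes only where it must:

1. **Sampling frame** — from a road-centreline network (GeoJSON), compute
   the 0.5 km network service area around each school, split roads into
   inter-junction street segments with odd/even sides (by house-number
   parity), and select intersections with ≥ 3 connecting roads for
   crossing audits. Boundary rules: an uninhabited partially-covered
   segment is excluded; a segment covered from both ends with residences at
   each end and majority coverage is extended to a full audit unit.
   Segments over 0.2 km are subdivided (halves to 0.4 km, thirds to
   0.6 km) for comparable audit units.
2. **Scoring** — ordinal audit items are recoded, summed into valence
   (positive/negative) sub-scales truncated at caps, sub-scales into
   section scores, and sections into a school-level overall grand score
   (maximum 210 points with the packaged default scheme). Cross-domain
   sub-scales sum school-level item averages across sections: pedestrian
   infrastructure (max 27), pedestrian design (max 22), bicycle facilities
   (max 11). Crossing scores are per-intersection sums over
   connecting-road audits and are shared between side scopes.
3. **Macro metrics** — corridor-polygon area (95 m road buffers),
   intersection density (junctions/km²), residential density
   (residences/km²), land-use mix as normalised Shannon entropy
   H = −Σ pᵢ ln pᵢ / ln k over k = 5 categories, and the composite
   walkability index: per school, z(intersection density) +
   z(residential density) + z(land-use mix).
4. **Statistics** — inter-rater intraclass correlation (one-way, two-way
   agreement, two-way consistency; exact F-based 95 % CIs) with Cicchetti
   bands (excellent ≥ 0.75, good 0.60–0.74, fair 0.40–0.59, poor < 0.40),
   and odd-vs-even concordance (Pearson, Spearman for designated
   non-normal measures) for the condensed protocol.
5. **Synthetic city** — a seeded generator of street grids, addresses,
   land-use mosaics and two-sided, two-rater audits with controllable
   between-side correlation ρ and rater noise, so the entire pipeline is
   testable end to end without external data.

## Worked example

```python
from mapssn import CityConfig, load_scheme, simulate_study

study = simulate_study(CityConfig(n_schools=12, between_side_rho=0.9,
                                  seed=7), load_scheme())
print(study.concordance[["measure", "odd_mean", "even_mean", "r", "p"]]
      .round(3).to_string(index=False))
```

prints (abridged):

```
                  measure  odd_mean  even_mean      r     p
           crossing_score    12.544     12.544    NaN   NaN
              grand_score    51.555     51.516  0.917 0.000
        pedestrian_design     4.504      4.465  0.758 0.004
            segment_score    15.176     15.243  0.810 0.001
```

Each row compares school-level scores computed from odd-side audits alone
against even-side audits alone. An odd/even correlation near 1 (here
r = 0.92 for the grand score across 12 simulated schools) means one audited
side represents the segment well — the evidence base for the condensed
protocol. The crossing row has no r because all connecting roads of an
intersection are audited once and shared between sides. The
`examples/` directory has one runnable script per capability (service
areas, scoring, concordance, reliability, macro metrics).

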
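# structome

Quantitative single-cell morphometry from serial ultrathin TEM sections
("structome analysis") for rod-shaped bacteria: per-section measurements in,
whole-cell structural profiles out, plus the statistics and growth-rate
calibration built on top of them.

## Who this is for

Electron microscopists and microbial cell biologists who reconstruct whole
cells from complete serial-section stacks (≈40 nm resin sections spanning a
cell pole to pole) and need reproducible numbers rather than image-software
spreadsheets: cell length, outer-membrane (OM) and plasma-membrane (PM)
diameters, membrane surface areas, compartment volumes, and cytoplasmic
ribosome counts and densities — and anyone comparing such profiles across
species or estimating growth rates of unculturable organisms from ribosome
density.

## The estimators

For a stack of `n` sections of thickness `t` (default 0.040 µm), with
per-section perimeters `p_i` and cross-sectional areas `a_i` traced at the
OM (whole cell) or PM (cytoplasm):

- **Length** — `n · t`, or an externally measured length carried with the
  stack.
- **Surface area** — trapezoid reconstruction,
  `S = Σᵢ (p_i + p_{i−1})/2 · t`.
- **Volume** — Cavalieri estimator, `V = Σᵢ a_i · t` (fl ≡ µm³).
- **Membrane shell volume** — `Σᵢ p_i · τ_i · t` with membrane thickness `τ`.
- **Periplasm** — by subtraction: `V_whole − V_cytoplasm − V_OM − V_PM`.
- **Ribosome density** — `total / V_cytoplasm × 0.1`, i.e. ribosomes per
  0.1 fl of cytoplasm, the species-characteristic statistic.
- **Growth calibration** — doubling time `y = a·e^(−b·x)` in minutes at
  ribosome density `x`, with published defaults `a = 4998.5`, `b = 0.002`;
  refittable by log-linear least squares and analytically invertible.

Because raw TEM stacks of this kind are rarely deposited, the package
includes a synthetic generator: spherocylinder cells with closed-form
surface (`2πrL`) and volume (`πr²(L−2r) + 4/3·πr³`), sliced into
mid-plane-sampled section stacks with optional lognormal measurement noise
and Poisson/multinomial ribosome placement. Every estimator is validated
against this analytic ground truth.

It also ships two read-only reference tables: the per-cell structome
profiles of seven serially sectioned *Mycolicibacterium smegmatis* cells,
and published species-level summaries (*M. tuberculosis*, *E. coli*,
*S. cerevisiae*, *Exophiala dermatitidis*, and two deep-sea Myojin
bacteria) for cross-species significance tests.

## Worked example

Simulate three cells with 3% tracing noise, quantify them, and predict a
doubling time:

```sh
$ cat cells.yaml
thickness_um: 0.04
noise_cv: 0.03
cells:
  - {cell_id: sim1, radius_om_um: 0.29, length_om_um: 3.54, seed: 11}
  - {cell_id: sim2, radius_om_um: 0.26, length_om_um: 2.8, seed: 12}
  - {cell_id: sim3, radius_om_um: 0.31, length_om_um: 5.1, seed: 13}

$ structome simulate --config cells.yaml --out stacks.tsv --no-timestamp
$ structome quantify --in stacks.tsv --out profiles.tsv --no-timestamp
$ cat profiles.tsv
cell_id  n_sections  length_um  diam_om_um  diam_pm_um  aspect_ratio  surf_om_um2  surf_pm_um2  vol_whole_fl  vol_om_fl  vol_periplasm_fl  vol_pm_fl  vol_cytoplasm_fl  ribosomes_total  ribosome_density
sim1     89          3.56       0.58        0.55        6.15          6.21         5.87         0.88          0.01       0.04              0.04       0.79              9290             1170
sim2     70          2.80       0.53        0.49        5.32          4.38         4.08         0.56          0.01       0.03              0.02       0.49              5640             1150
sim3     128         5.12       0.62        0.59        8.21          9.65         9.14         1.48          0.02       0.07              0.05       1.33              15590            1170
Average              3.83       0.58        0.54        6.56          6.75         6.36         0.97          0.01       0.05              0.04       0.87              10170            1160
SD                   1.18       0.05        0.05        1.49          2.67         2.56         0.47          0.01       0.02              0.02       0.42              5030             20
...
```

The first cell (radius 0.29 µm, length 3.54 µm, true density 1170/0.1 fl)
comes back with length 3.56 µm (89 sections × 0.04 µm), whole-cell volume
0.88 fl (analytic truth 0.884 fl) and density 1170 — the estimators recover
the generator's ground truth; the surface areas (6.21 vs analytic 6.45 µm²)
show the expected few-percent polar-cap deficit of the perimeter-trapezoid
method, which is documented, not silently corrected.

```sh
$ structome predict-doubling --density 1170
481.494
```

i.e. a cell population at 1170 ribosomes per 0.1 fl cytoplasm is predicted
to double every ≈ 8 h.  The same operations are available as a library:

```python
import structome as st

profiles = st.load_msmegmatis_profiles()
mtb = st.species_summary_map("M_tuberculosis")
density = st.summarize([p.ribosome_density for p in profiles])
print(st.t_test_from_summaries(density, mtb["ribosome_density"]))
# TestResult(statistic=4.359, df=9.113, p_value=0.00177, test_name='welch_t', ...)
```

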
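# striation

Quantitative analysis of laser-induced striation patterns in
fluorescence microscopy time-lapse stacks.

## The problem

A confocal laser-scanning microscope run at a very low scan resolution
(e.g. 32 × 32 pixels) with the laser left on between points draws a
pattern of equally spaced horizontal laser lines across the whole field
of view. Depending on the laser, this either damages DNA in stripes
through every nucleus simultaneously (micro-irradiation) or bleaches
the fluorophore in stripes (FRAP). Up to ~200 cells are photo-
manipulated at once, and the response of each — recruitment of
GFP-tagged repair proteins to the damage stripes, or diffusion of
unbleached molecules back into the bleached stripes — can be read out
automatically. This package implements that readout for people doing
DNA-damage-response, chromatin and photobleaching experiments: nucleus
segmentation, tracking, per-nucleus stripe fitting, the striation
measurement, curve summarisation and group statistics, plus a synthetic
scene generator that makes the whole pipeline testable without a
microscope.

## The measure of striation

For one nucleus at one time point, the image is rotated so the stripes
are vertical (Radon-transform orientation estimate), and the stripe
geometry — integer gauge *D* (distance between stripe centers) and
offset *P* (position of the first stripe center from the rightmost
nucleus boundary point) — is fitted by exhaustively maximising

    F(D, P) = mean intensity in the stripe bands / mean intensity in the nucleus,

with the stripe width a user-defined constant. The measure of
striation is the relative excess signal integrated density (SID) in the
stripes:

    MS = (J_meas − J_expt) / J_expt,
    J_expt = SID(nucleus) · area(stripes) / area(nucleus),

where *J*_meas is the measured SID inside the fitted stripe bands.
MS = 0 for a homogeneous nucleus, rises as protein is recruited to the
stripes, is negative when the stripes are bleached, and is invariant to
the nucleus's total brightness. The fit is repeated on every frame;
otherwise MS would decay spuriously as nuclei move and deform.

Per-nucleus MS(*t*) curves are summarised by **Amp** (maximum MS;
minimum for FRAP), **Tpeak** (minutes to the maximum), **Relax** (OLS
slope of MS(*t*) for *t* > Tpeak, falling back to *t* > 30 min when the
curve never peaks) and **Relax30** (slope after 30 min; for FRAP the
slopes over 1–30 and 1–60 min). Treated and mock-treated populations
are compared per parameter with the Kruskal–Wallis test at α = 0.05,
with concordance across biological replicates required before an effect
is reported.

## Worked example

```bash
python examples/simulate_and_analyze.py
```

renders a 12-nucleus field with programmed recruitment kinetics, runs
the full pipeline, and prints:

```
rendered 12 nuclei, 10 frames, gauge 16 px, stripe width 3 px
run counts: {'nuclei_found': 12, 'tracks_lost': 0, 'fit_failures': 0, 'curves_summarised': 12}
MS vs ground truth over 120 records: mean |error| = 0.027, max = 0.082
```

All 12 nuclei are found and tracked, and the measured MS follows the
programmed ground-truth curves to within a few hundredths of an MS unit
at a signal-to-noise ratio of ~10 — i.e. the readout is noise-limited,
not algorithm-limited. The other examples cover DDR curve parameters
(`ddr_curve_parameters.py`), FRAP recovery (`frap_recovery.py`) and the
screen-style group comparison (`compare_treatment_groups.py`).

The same pipeline is available from the shell:

```bash
striation simulate --config scene.yaml --out sim/
striation analyze --stack sim/stack.tif --times sim/times.csv --out results/
striation compare --treated results/curve_params.csv --mock mock/curve_params.csv --out summary.csv
```

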
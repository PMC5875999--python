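# iroakit

A toolkit for **Isotopic Ratio Outlier Analysis (IROA)** of GC/MS
metabolomics data: detecting mirrored ¹²C/¹³C isotopologue peak pairs,
reading backbone carbon counts and silylation counts from them, generating
ranked chemical formulae under IROA constraints, and scoring candidate
structures against observed EI fragment pairs.

## Who this is for, and the problem it solves

In untargeted GC/MS metabolomics most detected ions are never identified:
chemical background, derivatization artifacts and unknown metabolites are
hard to tell apart, and an accurate mass alone rarely pins down a formula.
IROA labeling solves the first problem chemically: one culture is grown on
randomized 95% ¹²C glucose and one on randomized 95% ¹³C glucose, the
extracts are mixed, methoximated/trimethylsilylated, and run on GC/MS.
Every *biological* metabolite then appears as a mirrored pair of binomial
isotopologue envelopes, and artifacts do not.

For an n-carbon backbone at ¹³C fraction *q*, the isotopologue intensities
follow Binomial(n, q). The all-¹²C anchor M₀ and all-¹³C anchor Mₙ are
spaced

    m(Mₙ) − m(M₀) = n · Δ,    Δ = 1.0033548 Da,

so the pair spacing reads out **n**. The first binomial term gives the
satellite ratio

    M₀₊₁ / M₀ = n·q/(1−q) + k·0.0854 + m·0.011,

where k silylation (TMS) groups and m methoxime groups each add a
first-order natural-abundance M+1 carryover. On the ¹³C side the backbone
contributes almost nothing at M+1, so Mₙ₊₁/Mₙ ≈ k·0.0854 inverts directly
to the TMS count. Together, (accurate m/z, n, k) constrain elemental
composition hard enough that a mass-window enumeration over
{C, H, N, O, Si, S} often leaves a single plausible formula — and observed
EI fragment pairs, each with its own carbon count, discriminate between
isomeric candidate structures predicted by external fragmentation tools.

## Worked example

Formula generation for the triple-silylated glutamic acid [MH]⁺ ion
measured at m/z 364.1793, with element ranges constrained by the IROA
evidence (5 backbone carbons + 3 TMS ⇒ C 14–15, Si 2–3):

```sh
$ iroa cfg --mz 364.1793 --tol-ppm 30 --C 14:15 --H 0:100 --N 0:4 --O 0:10 --Si 2:3 --S 0:2
rank,formula,theoretical_mz,ppm
1,C14H34NO4Si3,364.1796,-0.8
2,C15H34NO3SSi2,364.1798,-1.4
3,C15H36O2SSi3,364.1744,13.5
4,C15H32O6Si2,364.1737,15.4
5,C14H32N2O5Si2,364.185,-15.7
6,C14H34N3S2Si2,364.1733,16.5
7,C14H36N2OSSi3,364.1856,-17.3
8,C15H36N2S2Si2,364.1858,-17.8
```

Eight compositions fit at 30 ppm; the correct one (triple-TMS glutamate,
C₁₄H₃₄NO₄Si₃) ranks first at −0.8 ppm. Tightening to `--tol-ppm 5`, the
accuracy a high-resolution instrument supports, leaves only the top two.

Simulating a mixed-sample CI spectrum of the four bundled reference
metabolites and detecting the pairs:

```sh
$ iroa simulate --out-spectrum s.csv --out-manifest m.json --seed 7
$ iroa find-pairs s.csv
m0_mz,mn_mz,n_carbons,...,obs_mnp1_ratio,est_tms,score,...
351.184245,356.201086,5,...,0.2503,3,0.995,...
276.181528,282.201991,6,...,0.1777,2,0.943,...
274.129707,279.146084,5,...,0.1919,2,0.935,...
364.178948,369.196272,5,...,0.2474,3,0.931,...
```

All four planted metabolites are recovered with the correct backbone
carbon count (column `n_carbons`) and silylation count (`est_tms`,
inverted from the ¹³C-side M+1 ratio: e.g. 0.2503/0.0854 ≈ 3), despite
20 artifact peaks, 1 ppm mass jitter and 5% intensity noise. Artifact-only
spectra yield an empty report.

The other subcommands: `iroa annotate` ranks externally predicted
candidate EI spectra (MSP/CSV) against an observed EI-IROA spectrum, and
`iroa tms-count --ratio 0.171` inverts a single satellite ratio (→ 2).
Everything is also available as a library; see `docs/methods.md` for the
model, vetting rules, parameter defaults and limitations.

## Layout

| Module | Role |
| --- | --- |
| `iroakit.isotope_model` | binomial envelopes, mirror symmetry, M+1 carryover, pair-spacing arithmetic |
| `iroakit.spectra_io` | MSP / CSV peak tables / centroid mzML readers and writers |
| `iroakit.pair_finder` | IROA pair detection, carbon-count and TMS inference, pair scoring |
| `iroakit.formula_gen` | bounded formula enumeration, IROA-constrained element ranges |
| `iroakit.fragment_annotator` | EI fragment pairs, dot-product/Jaccard scores, candidate ranking |
| `iroakit.synthetic_data` | ground-truth simulator and bundled reference metabolites |
| `iroakit.cli` | `iroa simulate | find-pairs | cfg | annotate | tms-count` |
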
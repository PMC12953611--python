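# irute

Simulation and reconstruction toolkit for **motion-gated, dual-echo
inversion-recovery ultrashort-echo-time (IR-UTE) myelin-weighted MRI**.

Myelin protons have T2* below ~0.3 ms at 3 T and roughly a tenth of the
proton density of free water, so myelin is invisible to conventional
sequences and its low-SNR direct imaging is exquisitely sensitive to head
motion. The method studied here combines three ingredients:

1. **Segmented IR-UTE with dual-echo subtraction.** An adiabatic inversion
   nulls long-T2 white-matter water at an inversion time TI; ultrashort-T2*
   species (myelin, bone) are *saturated* rather than inverted and recover
   quickly. Each inversion is followed by a segment of N low-flip-angle
   radial spokes around the null point, each collecting two echoes
   (TE₁ ≈ 0.03 ms, TE₂ ≈ 2–3 ms). The magnitude subtraction
   |TE₁| − |TE₂| cancels long-T2* signal and isolates myelin.
2. **1D superior–inferior (SI) projection navigator.** One extra readout at
   the end of every segment yields an SI projection profile; the amplitude
   at a fixed reference pixel tracks head position at zero time cost.
   Threshold gating keeps the longest stable plateau of that trace and
   discards motion-corrupted segments.
3. **Bit-reversed view ordering.** Reversing the binary digits of the spoke
   index pseudo-randomizes the acquisition order, so a temporally
   contiguous block of rejected spokes is dispersed over k-space instead of
   opening a coherent angular sector (which would cause streaks).

The package provides a procedural six-tissue digital head phantom, an
event-based (analytically exact) Bloch engine for the segmented sequence,
center-out radial trajectories with sequential/bit-reversed ordering, the
navigator/gating simulation, Kaiser–Bessel gridding reconstruction with
Pipe–Menon iterative density compensation, and the image-quality metrics
used to score motion robustness (SSIM, myelin/GM CNR, 10–90% edge rise
distance, PSF side-lobe measures). Everything is generated in code — no
external data are required.

## Worked example

The segmented steady state shifts the white-matter null far below the
textbook single-shot value TI = T1·ln 2:

```python
from irute import SequenceParams, null_time_fully_recovered, null_time_steady_state
from irute.phantom import default_tissue_table

wm = next(c for c in default_tissue_table() if c.name == "WM_L")
params = SequenceParams()          # 15 deg, TR 1000 ms, 21 spokes / 6 ms
print(f"WM_L T1                     : {wm.T1:.0f} ms")
print(f"fully recovered null (T1ln2): {null_time_fully_recovered(wm.T1):.1f} ms")
print(f"segmented steady-state null : {null_time_steady_state(params, wm):.1f} ms")
```

```
WM_L T1                     : 850 ms
fully recovered null (T1ln2): 589.2 ms
segmented steady-state null : 348.7 ms
```

Repeated low-flip excitations keep Mz partially saturated between
inversions, so the zero crossing arrives ~240 ms earlier — which is why TI
must be tuned by Bloch simulation rather than by T1·ln 2.

The headline motion-robustness mechanism, at the full simulation scale
(220×220 matrix, 692 spokes, 10% contiguous spoke rejection):

```python
from irute.experiments import ordering_comparison
res = ordering_comparison(size=220, seed=0, fraction=0.10)
for o in ("sequential", "bit_reversed"):
    r = res[o]
    print(f"{o:13s} SSIM={r['ssim']:.3f}  peak side-lobe={r['peak_sidelobe']:.4f}")
```

```
sequential    SSIM=0.709  peak side-lobe=0.0546
bit_reversed  SSIM=0.961  peak side-lobe=0.0357
```

Rejecting the same 10% of spokes costs the sequentially ordered scan a
quarter of its structural similarity to the fully sampled reference (a
missing angular wedge → coherent streaks, visible as a high peak PSF
side-lobe), while the bit-reversed scan barely degrades.

## Command line

Every stage is also a config-driven subcommand (YAML config, flags
override; the resolved config and a manifest are echoed next to the
outputs):

```bash
irute phantom   --config config.yaml      # NIfTI labels + tissue CSV
irute simulate  --config config.yaml      # dual-echo k-space (npz) + tables
irute gate      --config config.yaml      # navigator trace, gating mask, plot
irute recon     --config config.yaml      # echo-1/echo-2/myelin NIfTI images
irute evaluate  --config config.yaml      # ordering-comparison metrics CSV
irute reproduce fig3|fig4bc|fig4de        # simulation figure panels
```

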
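# entropix

Entropy-rate and mutual-information estimation for neuroscience data, two
ways:

* the **direct method** — plug-in Shannon entropy computed over a grid of
  probability spaces (recording fraction *Size*, quantization range *v*,
  word length *T*) followed by three quadratic extrapolations to
  1/Size → 0, 1/v → 0 and 1/T → 0, yielding an entropy rate in
  bits/sample; applied across repeated trials it gives the noise entropy
  rate, and R = R_S − R_N estimates the stimulus–response information
  transfer rate;
* the **PNG Rate** — the size on disk of a minimal losslessly compressed
  grayscale PNG divided by its pixel count (bytes/pixel). By the source
  coding theorem a lossless code cannot beat entropy, so the PNG Rate is
  a fast linear proxy for the entropy rate; saving the trials × time
  image, rotating it 90° and saving again turns the same trick into a
  mutual-information estimate (signal minus noise rate).

The package bundles everything needed to benchmark the two estimators
against known ground truth: seeded white-noise generators with closed-form
entropies, a conductance-based spiking neuron with lognormal synaptic
bombardment (entropy-vs-rate, frozen-input MI, and synaptic-efficacy
protocols), a place-field random-walk simulator with Skaggs I_sec and a
pairing-image construction for compression-based spatial information, and
2-D image-complexity profiles (cylindrical anamorphosis, tiling, Sholl
comparison) for histology-style data.

Who it is for: experimenters who want a quick, assumption-free readout of
entropy or information *changes* across conditions without hand-tuning a
bias-correction estimator — plus the direct method as the in-package
control.

## Worked example

```python
import numpy as np
from entropix import (DiscreteSignal, NoiseSpec, uniform_noise,
                      entropy_rate_direct, GrayImage, png_rate)

# the "04050405" toy string: entropy depends on the probability space
from entropix import quantize, make_words, shannon_entropy
sig = DiscreteSignal([0, 4, 0, 5, 0, 4, 0, 5])
for v, T in [(6, 1), (2, 1), (6, 2), (2, 2)]:
    h = shannon_entropy(make_words(quantize(sig, v), T))
    print(f"H(v={v}, T={T}) = {h:.1f} bits")

# direct method on 500 points of binary white noise (true rate: 1 bit)
noise = uniform_noise(NoiseSpec(500, levels=2, seed=0))
est = entropy_rate_direct(noise)
print(f"direct estimate: {est.rate:.4f} bits/sample ({est.method_tag})")

# PNG Rate of 10,000 pixels of the same family
img_sig = uniform_noise(NoiseSpec(10_000, levels=2, seed=0))
img = GrayImage(img_sig.samples.reshape(100, 100).astype(np.uint8))
print(f"PNG Rate: {png_rate(img).rate_bytes_per_pixel:.4f} bytes/pixel")
```

prints

```
H(v=6, T=1) = 1.5 bits
H(v=2, T=1) = 1.0 bits
H(v=6, T=2) = 1.0 bits
H(v=2, T=2) = 0.0 bits
direct estimate: 0.9600 bits/sample (linear_last2)
PNG Rate: 0.1723 bytes/pixel
```

The four toy entropies show why quantization and word length must be
extrapolated away rather than chosen; the 500-point estimate sits on the
true 1 bit/sample; and the 0.17 bytes/pixel PNG Rate is the stable
compression cost of a 1-bit/pixel source (file overhead included — an
all-zero 100 × 100 image costs exactly 90 bytes).

Command line equivalents:

```
entropix synth --levels 2 --n 10000 --seed 1 -o sig.csv
entropix qem sig.csv --sampling-rate 10000
entropix pngrate sig.csv --depth 8 --sampling-rate 10000
entropix simulate --protocol mi --rates 1,5,10,20 --trials 20 --seed 7
entropix experiment fig1d --scale 1 --seed 1 -o results
```

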
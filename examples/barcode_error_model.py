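"""The analytic barcode-error model, end to end.

Chains the model's three uses: accumulate a per-stage polymerase error rate
over a whole duplex protocol, predict the fraction of 24-bp barcodes that
carry at least one error (and what that does to the family count of a small
hypothetical experiment), and invert the model to estimate the error rate
from an observed singleton-family fraction.
"""

from duplexkit import (
    cumulative_error,
    erroneous_fraction,
    expected_observed_families,
    invert_for_E,
    singleton_error_estimate,
)

# 30 PCR cycles + 1 sequencing reaction at 0.1 % error per base per stage
E_cum = cumulative_error(0.001, 31)
print(f"cumulative per-base error rate over 31 stages: {100 * E_cum:.2f} %")

# chance that a 24-bp duplex barcode (two 12-bp tags) picks up >= 1 error
r = erroneous_fraction(E_cum, 24)
print(f"fraction of erroneous barcodes:                {100 * r:.1f} %")

# 10 fragments sequenced into 100 read pairs: every erroneous barcode is
# (almost certainly) unique and founds an artifactual singleton family
n = expected_observed_families(10, 100, r)
print(f"expected families for 10 fragments/100 pairs:  {n} (10 real + {n - 10} artifacts)")

# inversion: a run with 1,717,170 singleton families among 17,385,100 read
# pairs implies this cumulative per-base error rate
r_hat = singleton_error_estimate(1_717_170, 17_385_100)
E_hat = invert_for_E(r_hat, 24)
print(f"singleton-based erroneous-barcode fraction:    {r_hat:.3f}")
print(f"implied cumulative per-base error rate:        {100 * E_hat:.2f} %")
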
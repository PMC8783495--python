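"""Founder allele-frequency spectrum for a bottlenecked domestic population.

Inverse-CDF knots (257 equally spaced quantiles) of the site frequency
spectrum observed among segregating biallelic variants in a sample of 6000
diploids from a coalescent simulation of a generic domestic-animal
demography: effective population size 100 at present, 500 at 100
generations ago, then increasing stepwise to 1e5 at one million
generations ago.  Pooled over 60 independent msprime replicates (14298
segregating sites); regenerate with scripts/derive_generic_spectrum.py.

The recent bottleneck leaves a U-shaped spectrum with substantial
intermediate-frequency variation (mean heterozygosity 2pq of about 0.24),
very different from the 1/q spectrum of a constant-size population.
"""

import numpy as np

GENERIC_SPECTRUM_QUANTILES = np.array([
    8.33333e-05, 8.33333e-05, 8.33333e-05, 8.33333e-05, 8.33333e-05, 8.33333e-05, 8.33333e-05, 8.33333e-05,
    8.33333e-05, 0.000166667, 0.000166667, 0.000166667, 0.000166667, 0.000166667, 0.00025, 0.00025,
    0.00025, 0.000333333, 0.000333333, 0.000416667, 0.0005, 0.0005, 0.000583333, 0.000666667,
    0.000666667, 0.00075, 0.000916667, 0.001, 0.00116667, 0.00125, 0.0015, 0.00166667,
    0.00183333, 0.00208105, 0.00233333, 0.00258333, 0.00295964, 0.00333333, 0.00366667, 0.00408333,
    0.0045, 0.005, 0.00583333, 0.00658333, 0.00716667, 0.008, 0.00875, 0.00958333,
    0.0105573, 0.0120833, 0.0134167, 0.0135, 0.0135833, 0.0144167, 0.0154167, 0.0158018,
    0.0179557, 0.0180833, 0.0188607, 0.0211667, 0.0214883, 0.0236423, 0.0248333, 0.0264167,
    0.0281667, 0.0308333, 0.0319167, 0.0341494, 0.0386667, 0.0411667, 0.0414167, 0.0460306,
    0.0497734, 0.0539167, 0.0544167, 0.0562624, 0.0619167, 0.06275, 0.06275, 0.06275,
    0.06275, 0.0643333, 0.0664167, 0.0735833, 0.0745, 0.0765, 0.0789167, 0.0840833,
    0.0840833, 0.0845, 0.0889167, 0.0929167, 0.0929167, 0.0929167, 0.0929167, 0.0929167,
    0.0930833, 0.0959167, 0.0990833, 0.10325, 0.106294, 0.110551, 0.120083, 0.12525,
    0.13075, 0.13075, 0.13075, 0.142917, 0.150667, 0.158083, 0.161667, 0.165424,
    0.16575, 0.169417, 0.18625, 0.197417, 0.206527, 0.216167, 0.218667, 0.221417,
    0.229417, 0.232083, 0.232083, 0.233667, 0.23825, 0.239833, 0.239833, 0.2475,
    0.25, 0.257167, 0.258583, 0.264, 0.264667, 0.26475, 0.26475, 0.26475,
    0.264917, 0.269366, 0.278663, 0.283, 0.2875, 0.2925, 0.309167, 0.314083,
    0.314083, 0.316, 0.325417, 0.330333, 0.337, 0.34025, 0.34025, 0.341495,
    0.358, 0.36025, 0.370167, 0.372583, 0.372667, 0.372667, 0.38275, 0.38275,
    0.39375, 0.417833, 0.417833, 0.422417, 0.423333, 0.42375, 0.43125, 0.4435,
    0.456, 0.4565, 0.467083, 0.4705, 0.4705, 0.4705, 0.4705, 0.480673,
    0.485417, 0.485417, 0.4935, 0.502167, 0.50325, 0.5065, 0.510333, 0.51603,
    0.52675, 0.5295, 0.5295, 0.5295, 0.530458, 0.534833, 0.544, 0.567167,
    0.57625, 0.576667, 0.577583, 0.58175, 0.582167, 0.593499, 0.61725, 0.627333,
    0.629833, 0.629833, 0.63975, 0.642043, 0.65975, 0.65975, 0.65975, 0.67275,
    0.674583, 0.685667, 0.70328, 0.709333, 0.7185, 0.735083, 0.73525, 0.73525,
    0.735333, 0.735333, 0.74025, 0.741417, 0.742833, 0.7525, 0.7525, 0.76175,
    0.767917, 0.781333, 0.818917, 0.83425, 0.841917, 0.86925, 0.86925, 0.86925,
    0.89675, 0.900917, 0.907083, 0.907083, 0.907083, 0.907083, 0.907083, 0.915917,
    0.915917, 0.9235, 0.9255, 0.935667, 0.936333, 0.93725, 0.93725, 0.93725,
    0.93725, 0.946083, 0.967503, 0.975167, 0.975167, 0.984583, 0.984583, 0.9865,
    0.993167,
])
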
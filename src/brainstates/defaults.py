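"""Study-wide default constants.

Every analysis parameter with a conventional value in 7 T block-design TVFC
work lives here so that nothing is hard-coded inside the pipeline stages.
"""

# Morlet filterbank
OMEGA0 = 6.0            # base frequency of the complex Morlet kernel
N_SCALES = 15           # log-spaced scales spanning the filterbank
F_MIN = 0.007           # Hz, slowest center frequency
F_MAX = 0.15            # Hz, fastest center frequency

# Cone-of-influence / smoothing-edge trimming
TRIM_TIME = 120         # samples dropped at each temporal edge
TRIM_SCALES = 2         # scales dropped at each spectral edge

# Topological distances
N_SLICES = 20           # projection directions for the sliced-Wasserstein mean
MAX_HOMOLOGY_DIM = 2

# State-space segmentation
GRID_SIZE = 256         # Gaussian density grid (longer axis)
BANDWIDTH_FACTOR = 0.08  # KDE bandwidth as a multiple of the per-axis SD

# Statistics
N_PERMUTATIONS = 300
N_BOOTSTRAPS = 256
ALPHA = 0.05

# Acquisition conventions (7 T block-design study emulated by the generator)
TR = 1.5                # seconds per sample
BAND = (0.009, 0.08)    # Hz, low-frequency BOLD fluctuation band
BLOCK_DURATION = 180.0  # seconds per stimulus block
INSTRUCTION_DURATION = 12.0  # seconds per instruction block

# Gordon 333-region cortical atlas: parcels with no coverage in some
# volunteers (0-indexed) are dropped from every dataset.
ATLAS_N_REGIONS = 333
ATLAS_EXCLUDED_REGIONS = (133, 296, 299, 302, 304)

TRAIN_SUBSAMPLE = 100   # per-volunteer training points for the embedding
N_REMOVED_PRESENTATIONS = 2  # one math + one memory block per volunteer
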
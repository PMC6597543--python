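"""Published specimen-level index values for the Ogasawara study system.

The bundled table carries the six genome-vulnerability indices reported per
RNA-seq specimen for six endangered Ogasawara island endemics and six
widespread non-endangered congeners (four genera: Ajuga, Crepidiastrum,
Calanthe, Melastoma).  Specimen labels record the sequencing read length
(90/100/150 bp paired-end).  The statistical comparison layer is exactly
recomputable from these rows: specimen means give species values, and the
within-genus EIE x NE direction vectors feed the cross-genus sign tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import species_table_from_specimens

#: published species-average rows (3 d.p.), used to cross-check aggregation
PUBLISHED_SPECIES_AVERAGES = {
    "A. boninsimae": (0.710, 0.022, 0.677, 0.043, 0.459, 0.370),
    "A. pygmaea": (0.720, 0.026, 0.654, 0.041, 0.422, 0.354),
    "A. shikotanensis": (0.741, 0.440, 0.503, 0.017, 0.319, 0.200),
    "C. grandicollum": (0.676, 0.168, 0.601, 0.029, 0.404, 0.261),
    "C. ameristophyllum": (0.721, 0.133, 0.599, 0.024, 0.386, 0.260),
    "C. linguifolium": (0.687, 0.129, 0.593, 0.030, 0.377, 0.244),
    "C. lanceolatum": (0.759, 0.254, 0.490, 0.020, 0.278, 0.190),
    "C. keiskeanum": (0.717, 0.283, 0.512, 0.017, 0.320, 0.202),
    "C. hoshii": (0.709, 0.128, 0.581, 0.026, 0.357, 0.255),
    "C. triplicata": (0.752, 0.256, 0.506, 0.023, 0.263, 0.211),
    "M. tetramerum": (0.701, 0.100, 0.596, 0.019, 0.376, 0.255),
    "M. candidum": (0.704, 0.361, 0.496, 0.013, 0.292, 0.208),
}


def load_specimen_indices() -> pd.DataFrame:
    """Per-specimen index table (35 specimen rows, 12 species)."""
    with resources.files("genovuln.data").joinpath("ogasawara_indices.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_species_table() -> pd.DataFrame:
    """Species-value table: specimen means per species (single specimens pass through)."""
    return species_table_from_specimens(load_specimen_indices())
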
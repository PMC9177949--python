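"""AAL90 atlas tables: region labels, six-lobe module lookup, centroid export.

The 90-region automated anatomical labeling parcellation (cerebrum only,
cerebellum omitted) is the node definition used throughout the package.
Regions are grouped into six anatomical modules — frontal, prefrontal,
subcortical, temporal, occipital and parietal lobes — for the modular
connection-strength analysis.

The packaged centroid table (``aal90_centroids_synthetic.csv``) is a
synthetic stand-in used only for BrainNet Viewer ``.node`` exports: it
carries published MNI coordinates for the regions this package's reference
analyses mention and zeros elsewhere.  It is not a measured atlas.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

N_NODES = 90
N_MODULES = 6
MODULE_NAMES = (
    "frontal",
    "prefrontal",
    "subcortical",
    "temporal",
    "occipital",
    "parietal",
)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("presbynet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_module_table() -> pd.DataFrame:
    """Return the packaged ``roi_label,module`` lookup (90 rows, 6 modules)."""
    return _read_packaged("aal90_modules.csv")


def load_centroids() -> pd.DataFrame:
    """Return the synthetic centroid table (``roi_label,x,y,z``)."""
    return _read_packaged("aal90_centroids_synthetic.csv")


def roi_labels() -> list[str]:
    """The 90 AAL region labels in atlas order."""
    return load_module_table()["roi_label"].tolist()
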
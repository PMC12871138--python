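"""Small bundled reference tables.

``plasma_concentration_minicatalog.tsv`` is a hand-assembled mini-catalog
of example absolute mouse plasma concentrations (annotation-catalog
schema); it is a stand-in for a full published plasma-concentration atlas
and covers only the handful of well-known marker proteins needed to
calibrate the dynamic-range rank analysis.

``disease_associations_synthetic.tsv`` is a synthetic fixture in the
schema of a large plasma proteome-phenome association atlas (protein,
disease, chapter, odds ratio, adjusted p, cohort size).  It exists so the
disease-association join can be exercised without the external resource;
its statistics are illustrative inputs, never computed by this package.
"""

from importlib.resources import files

import pandas as pd

from ..io_tables import AnnotationCatalog, read_annotation_catalog
from ..annotate import read_disease_atlas


def _path(name: str):
    return files(__package__).joinpath(name)


def load_plasma_concentration_minicatalog() -> AnnotationCatalog:
    """Annotation catalog carrying example absolute plasma concentrations."""
    return read_annotation_catalog(_path("plasma_concentration_minicatalog.tsv"))


def load_disease_association_fixture() -> pd.DataFrame:
    """Synthetic disease-association table in the external-atlas schema."""
    return read_disease_atlas(_path("disease_associations_synthetic.tsv"))
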
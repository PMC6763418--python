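"""Bundled alphabet collections.

The main dataset is a *reconstruction* of 34 simplified amino-acid
alphabets published across three decades of literature (textbook chemistry
classes, substitution-matrix clusterings, structure-alignment and
protein-block reductions, contact-potential groupings). Groupings were
re-assembled from the source publications; where a study's exact partition
could not be recovered verbatim, a chemically plausible partition of the
size favored by that study stands in. It is a synthetic stand-in for the
original curated table and is labelled as such in the fixture file.
"""

from __future__ import annotations

from importlib import resources

from .alphabet_io import AlphabetCollection, loads_collection

_FIXTURE = "published34_reconstruction.tsv"


def published_collection() -> AlphabetCollection:
    """The bundled 34-alphabet reconstruction (see module docstring)."""
    text = (
        resources.files("redalph").joinpath("data").joinpath(_FIXTURE).read_text()
    )
    return loads_collection(text)
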
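"""coralmir: small-RNA read QC, hairpin-based miRNA discovery, conservation
matching, accessibility-energy (ddG) target prediction and decorrelated GO
enrichment, exercised end to end on synthetic data with planted truth.
"""

from importlib import resources

__version__ = "0.1.0"


def bundled_path(name: str):
    """Path to a bundled data file (e.g. the S. pistillata mature set)."""
    return resources.files("coralmir").joinpath("data", name)
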
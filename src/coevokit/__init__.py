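"""coevokit — co-evolution analysis of two gene families across species.

Copy-number concordance testing, identity-vector and mirror-tree
correlations with permutation nulls, paralog-aware expression
quantification, and a simulator of coupled gene-family evolution.
"""

from importlib import resources

__version__ = "0.1.0"


def packaged_copy_panel_path():
    """Path to the bundled 8-species eutherian Tex19/Sectm1 copy panel."""
    return resources.files("coevokit.data") / "eutheria_copy_profiles.tsv"
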
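"""amdcomp: comparative metagenome/metatranscriptome profiling of microbial
communities — relative abundance, pairwise Fisher indicator screens,
transcriptional-activity ranking, and correlation-distance clustering."""

from importlib import resources

__version__ = "0.1.0"

from . import abundance, activity, differential, ingest, multivariate, pipeline, simulate  # noqa: F401,E402


def reference_geochemistry_path():
    """Path to the bundled four-site acid-mine-drainage geochemistry table."""
    return resources.files("amdcomp") / "data" / "amd_geochemistry.tsv"
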
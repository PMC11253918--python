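"""Tiny checked-in example files for documentation and smoke tests.

The radiometry file holds 5 simulated reads (one channel, 3 Edman
cycles) for the peptide ``NH2-A{azK}*|`` under mild error rates; it is
small enough to inspect by eye and is used by the CLI examples in the
README.  All files are synthetic.
"""

from importlib import resources


def fixture_path(name: str):
    """Filesystem path of a named fixture file."""
    return resources.files(__package__) / name


EXAMPLE_READS = "example_reads.tsv"
EXAMPLE_PARAMS = "example_params.json"
EXAMPLE_CHANNELS = "example_channels.json"
EXAMPLE_PEPTIDE = "NH2-A{azK}*|"
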
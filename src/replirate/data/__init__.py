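"""Packaged fixtures: the helicase-assay template and its qPCR primer table.

The FASTA holds the 4984-bp ScaI-linearised assay plasmid (pAWM36) carrying a
synthetic origin and five cassettes of four tandem MseI (TTAA) sites at
nominal distances of 200-2000 bp from the origin. The TSV holds the six qPCR
primer pairs (five cassette-flanking pairs plus one control pair annealing
away from any MseI site).
"""

from importlib.resources import files
from pathlib import Path


def pawm36_fasta_path() -> Path:
    """Path to the packaged assay-template FASTA."""
    return Path(str(files(__package__) / "pAWM36.fasta"))


def assay_primers_path() -> Path:
    """Path to the packaged primer-table TSV."""
    return Path(str(files(__package__) / "assay_primers.tsv"))
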
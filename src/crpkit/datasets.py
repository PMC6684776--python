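"""Bundled reference data.

Ships with the package:

* the five characterised CRP marker sequences (astratides aM1/bM1 from
  Radix Astragali, hedytides hP1/hP2 from Radix Hedysarum, achyranthes aB1
  from Achyranthes bidentata) as FASTA;
* the published UPLC method-validation QC table (intra-/inter-day observed
  mean +/- SD, RSD%, accuracy% for five standard compounds at three spike
  levels);
* the published PLS-DA preprocessing comparison (RMSEC/RMSECV/RMSEP and r²
  for five preprocessing recipes).

The tables are inputs for recomputing and checking the validation
statistics, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .markers import PeptideSequence, read_fasta

__all__ = ["load_reference_peptides", "load_uplc_qc", "load_preprocessing_comparison"]


def _data_path(name: str):
    return resources.files("crpkit.data").joinpath(name)


def load_reference_peptides() -> dict[str, PeptideSequence]:
    """The five bundled CRP marker sequences, keyed by name."""
    with resources.as_file(_data_path("crp_sequences.fasta")) as path:
        peptides = read_fasta(path)
    return {p.name: p for p in peptides}


def load_uplc_qc() -> pd.DataFrame:
    """Published QC rows: compound, spike level, period, observed mean/SD and
    the printed RSD%/accuracy% they summarise."""
    with resources.as_file(_data_path("uplc_validation_qc.csv")) as path:
        return pd.read_csv(path)


def load_preprocessing_comparison() -> pd.DataFrame:
    """Published PLS-DA fit statistics for five preprocessing recipes."""
    with resources.as_file(_data_path("plsda_preprocessing_comparison.csv")) as path:
        return pd.read_csv(path)
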
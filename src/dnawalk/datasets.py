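"""Bundled reference data.

One table ships with the package: published compositional statistics and
scaling exponents for the complete mitochondrial genomes of 32 vertebrate
species spanning seven taxonomic classes (amphibians, birds, fish,
marsupials, placental mammals, primates, reptiles). Columns:

    species, xi, H, alpha_RY, alpha_SW, alpha_KM, beta_RY, beta_SW, beta_KM

where ξ is the Chargaff (pyrimidine/purine) ratio, H the Shannon entropy
in bits, α the rescaled-range Hurst exponents and β the DFA exponents for
the RY/SW/KM walk rules. These measurements are the inputs from which the
evolutionary indices v1–v3 and the reference tree are recomputed; the
package never ships precomputed index values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_vertebrate_reference() -> pd.DataFrame:
    """Published per-species statistics for 32 vertebrate mtDNA genomes."""
    ref = resources.files("dnawalk") / "data" / "vertebrate_mtdna_reference.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
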
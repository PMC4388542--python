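import numpy as np
import pandas as pd
import pytest

from raftdiff.datamodel import ChannelDesign, PSMRecord


@pytest.fixture
def design():
    return ChannelDesign(
        experiment_id="exp1",
        channel_to_condition={"114": "KO", "113": "WT"},
        numerator_condition="KO",
        denominator_condition="WT",
    )


def make_psm(gene="Flot1", ko=200.0, wt=100.0, confidence=99.0, *,
             experiment_id="exp1", peptide="ACDEFGHIK", protein="P0001",
             is_decoy=False, is_contaminant=False):
    return PSMRecord(
        experiment_id=experiment_id, peptide=peptide, protein=protein,
        gene=gene, confidence=confidence,
        intensities={"114": ko, "113": wt},
        is_decoy=is_decoy, is_contaminant=is_contaminant,
    )


@pytest.fixture
def small_psm_frame():
    """Two experiments, two genes, hand-computable intensities."""
    rows = []
    for exp, chans in (("exp1", ("i113", "i114")), ("exp2", ("i113", "i114"))):
        for gene, pairs in (
            ("Flot1", [(100.0, 200.0), (50.0, 110.0), (80.0, 150.0)]),
            ("Hspa8", [(120.0, 121.0), (90.0, 88.0)]),
        ):
            for i, (wt, ko) in enumerate(pairs):
                rows.append({
                    "experiment_id": exp, "peptide": f"PEP{gene}{i}",
                    "protein": gene.upper(), "gene": gene,
                    "confidence": 99.0, chans[0]: wt, chans[1]: ko,
                    "is_decoy": False, "is_contaminant": False,
                })
    return pd.DataFrame(rows)[
        ["experiment_id", "peptide", "protein", "gene", "confidence",
         "i113", "i114", "is_decoy", "is_contaminant"]
    ]
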
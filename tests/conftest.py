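import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pamlcat import (
    Case,
    ClinicalRecord,
    Cohort,
    FusionCall,
    GenomicInterval,
    KaryotypeRecord,
    SomaticVariant,
    TandemDupCandidate,
)


def make_variant(
    gene="WT1",
    chrom="chr11",
    pos=32417945,
    ref="C",
    alt="T",
    alt_reads=20,
    total_reads=50,
    population_af=0.0,
    pathogenicity="pathogenic",
    variant_class="snv",
):
    return SomaticVariant(
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=alt_reads / total_reads,
        alt_reads=alt_reads,
        total_reads=total_reads,
        population_af=population_af,
        pathogenicity=pathogenicity,
        variant_class=variant_class,
    )


def make_clinical(**kwargs):
    defaults = dict(
        age_years=5.0,
        timepoint="diagnosis",
        mrd_positive=False,
        os_time=3.0,
        os_event=False,
        efs_time=3.0,
        efs_event=False,
        nonresponse=False,
        relapse_flag=False,
    )
    defaults.update(kwargs)
    return ClinicalRecord(**defaults)


@pytest.fixture
def three_case_cohort():
    """Small cohort: a fusion-defined case, a mutation case, an empty case."""
    cases = [
        Case(
            case_id="P001",
            fusions=[FusionCall("RUNX1", "RUNX1T1", True, 25, 40.0, "rna_fusion")],
            clinical=make_clinical(os_event=True, os_time=1.5),
        ),
        Case(
            case_id="P002",
            variants=[make_variant("NPM1", "chr5", 170837543, "C", "CTCTG",
                                   variant_class="indel")],
            tandem_dups=[
                TandemDupCandidate(
                    "FLT3", GenomicInterval("chr13", 28608219, 28608300), 15, 4.0, "itd"
                )
            ],
            clinical=make_clinical(timepoint="relapse", mrd_positive=True),
        ),
        Case(
            case_id="P003",
            karyotype=KaryotypeRecord(complex_karyotype=True, monosomy7=True,
                                      other_events=("del(5q)",)),
            clinical=make_clinical(mrd_positive=None, efs_time=None,
                                   efs_event=None),
        ),
    ]
    return Cohort(cases=cases)


@pytest.fixture(scope="session")
def default_synthetic():
    """Default synthetic cohort (n=500, seed 0), shared across tests."""
    import pamlcat

    return pamlcat.generate(pamlcat.GeneratorConfig(n_cases=500, seed=0))
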
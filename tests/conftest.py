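import pytest

from mdsrisk import (
    ClinicalPanel,
    CytogeneticsProfile,
    MutationCall,
    PatientRecord,
    load_coefficients,
    load_ipssr_table,
)


@pytest.fixture(scope="session")
def coeffs():
    return load_coefficients()


@pytest.fixture(scope="session")
def ipssr_table():
    return load_ipssr_table()


def make_record(
    pid="P1",
    blasts=1.0,
    hb=11.0,
    platelets=150.0,
    anc=2.0,
    cyto_category=1,
    del5q=False,
    minus7=False,
    del17p=False,
    complex_k=False,
    cnloh=False,
    mutations=(),
    assessed=None,
    endpoints=None,
):
    """A fully assessed, otherwise unremarkable patient; override what matters."""
    calls = tuple(
        MutationCall(pid, gene, vaf, mtype)
        for gene, vaf, mtype in (
            (m if len(m) == 3 else (m[0], m[1], "SNV")) for m in mutations
        )
    )
    return PatientRecord(
        patient_id=pid,
        clinical=ClinicalPanel(bm_blasts=blasts, hemoglobin=hb, platelets=platelets, anc=anc),
        cytogenetics=CytogeneticsProfile(
            ipssr_cyto_category=cyto_category,
            del5q=del5q,
            minus7_or_del7q=minus7,
            del17p=del17p,
            complex_karyotype=complex_k,
            tp53_cnloh=cnloh,
        ),
        mutations=calls,
        endpoints=endpoints,
        assessed_genes=assessed,
    )
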
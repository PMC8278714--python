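import numpy as np
import pandas as pd
import pytest

from boat.io import MarkerTable


def build_marker_table(records, accessions):
    """records: list of (marker_id, chromosome, calls list). Gene/position from the id."""
    from boat.io import parse_marker_id

    meta_rows, call_rows, index = [], [], []
    for mid, chrom, calls in records:
        gene, pos, _ = parse_marker_id(mid)
        index.append(mid)
        meta_rows.append(
            {
                "gene_id": gene,
                "chromosome": chrom,
                "position": pos,
                "allele_states": "/".join(sorted(set(calls) - {"N"})),
            }
        )
        call_rows.append(list(calls))
    meta = pd.DataFrame(meta_rows, index=pd.Index(index, name="marker_id"))
    meta["order_index"] = meta.groupby("chromosome").cumcount() + 1
    calls = pd.DataFrame(call_rows, index=meta.index, columns=accessions)
    return MarkerTable(meta, calls)


@pytest.fixture
def tiny_table():
    """Ten accessions, four markers incl. a hemi-SNP and a monomorphic marker."""
    acc = [f"a{i}" for i in range(10)]
    return build_marker_table(
        [
            ("Bo6g103650.1:2010:T", "C06", list("CCCCTTTYYN")),
            ("Bo6g103650.1:2400:G", "C06", list("AAGGGGGGGA")),
            ("Bo1g000010.1:100:A", "C01", list("AAAAAAAAAA")),
            ("Bo1g000010.1:900:C", "C01", list("CCCCCTTTTT")),
        ],
        acc,
    )


@pytest.fixture(scope="session")
def null_panel():
    from boat.synth import make_panel

    return make_panel("null", seed=11)


@pytest.fixture(scope="session")
def causal_panel():
    from boat.synth import make_panel

    return make_panel("causal_marker", seed=7)


@pytest.fixture(scope="session")
def structured_panel():
    from boat.synth import make_panel

    return make_panel("structured_confounded", seed=19)
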
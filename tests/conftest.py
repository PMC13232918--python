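import pandas as pd
import pytest

from bpqc.io_model import VISIT_COLUMNS


def make_visit_table(visits):
    """Build a long-format visit table from
    [(cohort, participant, visit, [(sbp, dbp), ...]), ...]."""
    rows = []
    for cohort, pid, vid, readings in visits:
        for i, (s, d) in enumerate(readings, start=1):
            rows.append((cohort, pid, vid, i, s, d))
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


@pytest.fixture
def two_visit_table():
    return make_visit_table(
        [
            ("A", "P1", "V1", [(120, 80), (130, 84)]),
            ("A", "P2", "V1", [(120, 80), (135, 82), (133, 84)]),
        ]
    )


@pytest.fixture
def csv_writer(tmp_path):
    def write(df, name="visits.csv"):
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    return write
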
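import numpy as np
import pytest

from agecjs import CaptureHistory, make_grid


@pytest.fixture
def grid5():
    """Five consecutive semesters starting 2012S1, single period."""
    return make_grid(2012, 1, 5)


@pytest.fixture
def grid22():
    """The full 2012-2022 study grid with three periods."""
    from agecjs import default_grid

    return default_grid()


def history_from_rows(rows, ages, grid):
    """Build a CaptureHistory from binary row tuples and ages at first capture."""
    y = np.array(rows, dtype=np.uint8)
    f = np.argmax(y, axis=1)
    ids = np.array([f"i{j}" for j in range(len(rows))], dtype=object)
    return CaptureHistory(ids=ids, y=y, f=f, age_at_first=np.asarray(ages), grid=grid)


@pytest.fixture
def history_builder():
    return history_from_rows
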
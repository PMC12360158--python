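import pytest

from tiproute import TaskMatrix, combined_distance, get_plate, random_task


@pytest.fixture
def plate96():
    return get_plate("96")


@pytest.fixture
def plate12():
    return get_plate("12")


def make_task(src, dst, triples):
    """Task from (source_well, dest_well, volume) triples."""
    return TaskMatrix.from_jobs(src, dst, triples)


@pytest.fixture
def diagonal3_12():
    """Three diagonal jobs on 12-well plates."""
    return make_task("12", "12", [(1, 1, 10.0), (5, 5, 20.0), (9, 9, 30.0)])


@pytest.fixture
def chain16_96():
    """16 transfers on 96-well plates admitting a two-cycle zero-cost order:
    source column 1 -> dest column 1 (jobs 0-7), column 2 -> column 2."""
    return make_task("96", "96", [(w, w, 50.0) for w in range(1, 17)])


@pytest.fixture
def random_task_small():
    return random_task("12", "12", 10, seed=42)


@pytest.fixture
def model_small(random_task_small):
    return combined_distance(random_task_small)
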
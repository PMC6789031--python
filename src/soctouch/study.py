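"""Study-design summary constants of the source dataset.

These printed totals are inputs for bookkeeping checks (the raw neural data
are not deposited): 1156 single units recorded over 7408 social facial-touch
episodes, giving 58,591 unique cell-touch pairs, an average of 51 touch
episodes per cell.
"""

N_UNITS = 1156
N_EPISODES = 7408
N_CELL_TOUCH_PAIRS = 58591
EPISODES_PER_CELL = 51

# behavioral statistics (s): median and interquartile range
TOUCH_DURATION_MEDIAN = 1.33
TOUCH_DURATION_IQR = (0.77, 2.53)
INTER_TOUCH_INTERVAL_MEDIAN = 4.68
INTER_TOUCH_INTERVAL_IQR = (1.24, 23.78)


def episodes_per_cell(n_pairs=N_CELL_TOUCH_PAIRS, n_units=N_UNITS) -> int:
    """Average number of touch episodes per recorded cell, rounded to the
    nearest integer."""
    return round(n_pairs / n_units)
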
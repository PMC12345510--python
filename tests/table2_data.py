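"""Published composition table of the four study mitogenomes.

Per (species, region): length (bp), percentages of a/t/c/g, AT and GC
content, and the printed AT-/GC-skews.  Used as frozen expected values
for the skew/content reproduction tests.
"""

# (species, region) -> (length, a, t, c, g, AT, GC, at_skew, gc_skew)
TABLE2 = {
    ("Nomia_thoracica", "whole_genome"): (17883, 44.03, 41.36, 9.32, 5.23, 85.39, 14.56, 0.031, -0.281),
    ("Nomia_thoracica", "PCGs"):         (11114, 38.44, 46.32, 8.25, 6.99, 84.76, 15.24, -0.093, -0.083),
    ("Nomia_thoracica", "site1"):        (3705, 41.69, 40.46, 7.68, 10.17, 82.15, 17.85, 0.015, 0.140),
    ("Nomia_thoracica", "site2"):        (3705, 25.41, 51.50, 13.55, 9.54, 76.91, 23.09, -0.339, -0.174),
    ("Nomia_thoracica", "site3"):        (3704, 48.23, 46.99, 3.53, 1.25, 95.22, 4.78, 0.013, -0.477),
    ("Nomia_thoracica", "tRNA"):         (1455, 45.36, 41.58, 5.57, 7.49, 86.94, 13.06, 0.043, 0.147),
    ("Nomia_thoracica", "rRNA"):         (2097, 42.87, 43.44, 4.49, 9.14, 86.31, 13.62, -0.007, 0.341),
    ("Nomia_thoracica", "CR"):           (2755, 44.07, 44.39, 7.33, 4.07, 88.46, 11.40, -0.004, -0.287),
    ("Lipotriches_guihongi", "whole_genome"): (19178, 43.68, 42.76, 9.24, 4.31, 86.44, 13.56, 0.011, -0.364),
    ("Lipotriches_guihongi", "PCGs"):    (11142, 39.31, 45.71, 8.23, 6.76, 85.01, 14.99, -0.075, -0.098),
    ("Lipotriches_guihongi", "site1"):   (3714, 43.81, 38.20, 8.21, 9.78, 82.02, 17.98, 0.068, 0.087),
    ("Lipotriches_guihongi", "site2"):   (3714, 24.53, 52.75, 13.36, 9.37, 77.28, 22.72, -0.365, -0.176),
    ("Lipotriches_guihongi", "site3"):   (3714, 49.57, 46.17, 3.13, 1.13, 95.74, 4.26, 0.035, -0.470),
    ("Lipotriches_guihongi", "tRNA"):    (1523, 45.24, 42.48, 5.25, 7.03, 87.72, 12.28, 0.031, 0.144),
    ("Lipotriches_guihongi", "rRNA"):    (2160, 43.26, 43.95, 4.27, 8.53, 87.20, 12.80, -0.008, 0.333),
    ("Lipotriches_guihongi", "CR"):      (3481, 42.23, 49.27, 8.07, 0.40, 91.50, 8.47, -0.077, -0.905),
    ("Lipotriches_capitata", "whole_genome"): (16492, 41.84, 44.56, 7.54, 6.02, 86.41, 13.55, -0.031, -0.112),
    ("Lipotriches_capitata", "PCGs"):    (11127, 38.02, 48.59, 6.52, 6.87, 86.61, 13.39, -0.122, 0.026),
    ("Lipotriches_capitata", "site1"):   (3710, 42.46, 40.43, 7.19, 9.91, 82.90, 17.10, 0.024, 0.159),
    ("Lipotriches_capitata", "site2"):   (3709, 25.48, 52.93, 12.10, 9.48, 78.41, 21.59, -0.350, -0.121),
    ("Lipotriches_capitata", "site3"):   (3708, 46.12, 52.39, 0.28, 1.21, 98.51, 1.49, -0.064, 0.620),
    ("Lipotriches_capitata", "tRNA"):    (1492, 44.24, 43.97, 4.56, 7.24, 88.20, 11.80, 0.003, 0.227),
    ("Lipotriches_capitata", "rRNA"):    (2116, 44.13, 43.53, 4.26, 8.08, 87.67, 12.34, 0.007, 0.310),
    ("Lipotriches_capitata", "CR"):      (1576, 43.46, 43.72, 6.79, 5.58, 87.18, 12.37, -0.003, -0.097),
    ("Dufourea_subclavicrus", "whole_genome"): (21192, 43.23, 39.32, 11.04, 6.35, 82.55, 17.38, 0.047, -0.270),
    ("Dufourea_subclavicrus", "PCGs"):   (11075, 38.09, 43.73, 10.48, 7.70, 81.82, 18.18, -0.069, -0.153),
    ("Dufourea_subclavicrus", "site1"):  (3692, 44.45, 36.15, 9.22, 10.19, 80.59, 19.41, 0.103, 0.050),
    ("Dufourea_subclavicrus", "site2"):  (3692, 24.21, 51.60, 14.39, 9.80, 75.81, 24.19, -0.361, -0.190),
    ("Dufourea_subclavicrus", "site3"):  (3691, 45.63, 43.44, 7.82, 3.12, 89.07, 10.93, 0.025, -0.430),
    ("Dufourea_subclavicrus", "tRNA"):   (1441, 42.61, 41.50, 6.94, 8.95, 84.11, 15.89, 0.013, 0.127),
    ("Dufourea_subclavicrus", "rRNA"):   (2047, 40.72, 42.92, 5.65, 10.73, 83.63, 16.37, -0.026, 0.310),
    ("Dufourea_subclavicrus", "CR"):     (6572, 40.73, 43.75, 8.31, 6.98, 84.48, 15.29, -0.036, -0.087),
}

# Cells the source table itself rounded from unprinted raw counts in a way
# the printed percentages cannot reproduce exactly; asserted within +/-0.002.
ARTIFACT_CELLS = {
    ("Lipotriches_guihongi", "CR", "gc"),
    ("Dufourea_subclavicrus", "tRNA", "gc"),
    ("Lipotriches_capitata", "site3", "gc"),
}
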
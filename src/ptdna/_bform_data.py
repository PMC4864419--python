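"""Frozen idealized B-form nucleotide geometry (level-0 helix frame).

Generated by scratch/build_geometry.py: Watson-Crick pairs from ideal
base fragments, C2'-endo sugars, backbone closed by least squares at
rise 3.38 A / twist 36 deg.  Do not edit by hand.
"""

import numpy as np

PARAMS = {'chi_G': np.float64(-111.6771), 'chi_A': np.float64(-113.7676), 'chi_C': np.float64(-111.8532), 'chi_T': np.float64(-114.7554), 'gamma': np.float64(39.19), 'beta': np.float64(170.7568), 'alpha': np.float64(-43.5129), 'dx': np.float64(-1.9447), 'dy': np.float64(-0.0083), 'tip': np.float64(-0.0049), 'roll': np.float64(-0.184), 'dxAT': np.float64(-0.0696), 'dyAT': np.float64(-0.0087), 'rollAT': np.float64(-0.0224)}

PAIR_UNITS = {
    'GC': [
        ('P', 'P', 1, (0.80815, 9.15527, -2.76194)),
        ('O1P', 'O', 1, (0.39278, 10.53875, -3.10643)),
        ('O2P', 'O', 1, (1.91459, 8.93580, -1.79610)),
        ("O5'", 'O', 1, (-0.47544, 8.37472, -2.22605)),
        ("C5'", 'C', 1, (-1.53861, 7.99750, -3.12102)),
        ("H5'", 'H', 1, (-1.11896, 7.48244, -3.98514)),
        ("H5''", 'H', 1, (-2.06095, 8.89203, -3.46025)),
        ("C4'", 'C', 1, (-2.51395, 7.08340, -2.41658)),
        ("H4'", 'H', 1, (-3.45850, 7.08540, -2.96057)),
        ("O4'", 'O', 1, (-1.97851, 5.73673, -2.33748)),
        ("C1'", 'C', 1, (-1.94474, 5.31402, -0.99044)),
        ("H1'", 'H', 1, (-2.82062, 4.74796, -0.67340)),
        ("C2'", 'C', 1, (-1.85584, 6.58419, -0.17222)),
        ("H2'", 'H', 1, (-0.82875, 6.94308, -0.10608)),
        ("H2''", 'H', 1, (-2.24556, 6.43610, 0.83489)),
        ("C3'", 'C', 1, (-2.72925, 7.54431, -0.97000)),
        ("H3'", 'H', 1, (-2.40724, 8.57662, -0.83308)),
        ("O3'", 'O', 1, (-4.09645, 7.43147, -0.59193)),
        ('N9', 'N', 1, (-0.79623, 4.42244, -0.81964)),
        ('C8', 'C', 1, (0.51843, 4.78073, -0.87982)),
        ('N7', 'N', 1, (1.27034, 3.73671, -0.68272)),
        ('C5', 'C', 1, (0.48514, 2.64980, -0.48491)),
        ('C6', 'C', 1, (0.74159, 1.28224, -0.23013)),
        ('N1', 'N', 1, (-0.31141, 0.45095, -0.07350)),
        ('C2', 'C', 1, (-1.58421, 0.92540, -0.17360)),
        ('N3', 'N', 1, (-1.83561, 2.19316, -0.41119)),
        ('C4', 'C', 1, (-0.84497, 3.07826, -0.56941)),
        ('O6', 'O', 1, (1.88432, 0.86635, -0.14769)),
        ('N2', 'N', 1, (-2.63379, 0.05597, -0.01764)),
        ('H8', 'H', 1, (0.88183, 5.78157, -1.06411)),
        ('H1', 'H', 1, (-0.15972, -0.49133, 0.10157)),
        ('H21', 'H', 1, (-3.54566, 0.37989, -0.08205)),
        ('H22', 'H', 1, (-2.46426, -0.88384, 0.15327)),
        ('P', 'P', 2, (0.68972, -9.24225, 2.78801)),
        ('O1P', 'O', 2, (0.23602, -10.61577, 3.12390)),
        ('O2P', 'O', 2, (1.81356, -9.04815, 1.83693)),
        ("O5'", 'O', 2, (-0.56726, -8.42921, 2.23756)),
        ("C5'", 'C', 2, (-1.63224, -8.02772, 3.11973)),
        ("H5'", 'H', 2, (-1.21118, -7.52492, 3.99036)),
        ("H5''", 'H', 2, (-2.18076, -8.90979, 3.45014)),
        ("C4'", 'C', 2, (-2.57564, -7.08842, 2.40501)),
        ("H4'", 'H', 2, (-3.52686, -7.06825, 2.93685)),
        ("O4'", 'O', 2, (-2.00623, -5.75520, 2.33594)),
        ("C1'", 'C', 2, (-1.94474, -5.33071, 0.99044)),
        ("H1'", 'H', 2, (-2.80227, -4.74259, 0.66354)),
        ("C2'", 'C', 2, (-1.87663, -6.60102, 0.17045)),
        ("H2'", 'H', 2, (-0.85792, -6.98499, 0.11661)),
        ("H2''", 'H', 2, (-2.24960, -6.44132, -0.84123)),
        ("C3'", 'C', 2, (-2.78360, -7.54094, 0.95472)),
        ("H3'", 'H', 2, (-2.48537, -8.58060, 0.81950)),
        ("O3'", 'O', 2, (-4.14264, -7.39366, 0.55943)),
        ('N1', 'N', 2, (-0.77196, -4.46696, 0.83639)),
        ('C2', 'C', 2, (-0.93523, -3.15533, 0.59066)),
        ('N3', 'N', 2, (0.11374, -2.34719, 0.44586)),
        ('C4', 'C', 2, (1.34967, -2.81770, 0.54081)),
        ('C5', 'C', 2, (1.55440, -4.18927, 0.79380)),
        ('C6', 'C', 2, (0.47866, -4.99680, 0.94305)),
        ('O2', 'O', 2, (-2.06255, -2.69783, 0.49791)),
        ('N4', 'N', 2, (2.42574, -1.97411, 0.38894)),
        ('H41', 'H', 2, (2.28093, -1.03168, 0.21155)),
        ('H42', 'H', 2, (3.32847, -2.32076, 0.46361)),
        ('H5', 'H', 2, (2.55531, -4.58872, 0.87447)),
        ('H6', 'H', 2, (0.61032, -6.04976, 1.14160)),
    ],
    'AT': [
        ('P', 'P', 1, (0.80475, 9.05748, -2.76374)),
        ('O1P', 'O', 1, (0.40578, 10.44554, -3.10917)),
        ('O2P', 'O', 1, (1.88344, 8.82531, -1.76989)),
        ("O5'", 'O', 1, (-0.49678, 8.27972, -2.26863)),
        ("C5'", 'C', 1, (-1.53711, 7.91448, -3.19487)),
        ("H5'", 'H', 1, (-1.09671, 7.40352, -4.05106)),
        ("H5''", 'H', 1, (-2.04559, 8.81413, -3.54154)),
        ("C4'", 'C', 1, (-2.53576, 7.00036, -2.52389)),
        ("H4'", 'H', 1, (-3.46516, 7.01118, -3.09328)),
        ("O4'", 'O', 1, (-2.00936, 5.65041, -2.44023)),
        ("C1'", 'C', 1, (-2.01430, 5.21780, -1.09591)),
        ("H1'", 'H', 1, (-2.90127, 4.65400, -0.80693)),
        ("C2'", 'C', 1, (-1.94134, 6.48155, -0.26625)),
        ("H2'", 'H', 1, (-0.91465, 6.83464, -0.16963)),
        ("H2''", 'H', 1, (-2.35900, 6.32820, 0.72881)),
        ("C3'", 'C', 1, (-2.78798, 7.45192, -1.08034)),
        ("H3'", 'H', 1, (-2.46468, 8.48153, -0.92712)),
        ("O3'", 'O', 1, (-4.16549, 7.34341, -0.74033)),
        ('N9', 'N', 1, (-0.87406, 4.31812, -0.90039)),
        ('C8', 'C', 1, (0.44253, 4.66025, -0.96503)),
        ('N7', 'N', 1, (1.18480, 3.61493, -0.74249)),
        ('C5', 'C', 1, (0.39339, 2.53909, -0.51583)),
        ('C6', 'C', 1, (0.62555, 1.18205, -0.23720)),
        ('N1', 'N', 1, (-0.42207, 0.38025, -0.07538)),
        ('C2', 'C', 1, (-1.65489, 0.83845, -0.17843)),
        ('N3', 'N', 1, (-1.92098, 2.09966, -0.44340)),
        ('C4', 'C', 1, (-0.93790, 2.97671, -0.62128)),
        ('N6', 'N', 1, (1.91531, 0.69228, -0.12811)),
        ('H8', 'H', 1, (0.81544, 5.65233, -1.17024)),
        ('H61', 'H', 1, (2.06301, -0.24577, 0.06913)),
        ('H62', 'H', 1, (2.67209, 1.28721, -0.25177)),
        ('H2', 'H', 1, (-2.47739, 0.15197, -0.04047)),
        ('P', 'P', 2, (0.66891, -9.19685, 2.74185)),
        ('O1P', 'O', 2, (0.22391, -10.57578, 3.06702)),
        ('O2P', 'O', 2, (1.76329, -8.98669, 1.76033)),
        ("O5'", 'O', 2, (-0.60330, -8.37315, 2.24481)),
        ("C5'", 'C', 2, (-1.64017, -7.98662, 3.16627)),
        ("H5'", 'H', 2, (-1.19194, -7.49975, 4.03237)),
        ("H5''", 'H', 2, (-2.17947, -8.87402, 3.49761)),
        ("C4'", 'C', 2, (-2.60382, -7.03400, 2.49767)),
        ("H4'", 'H', 2, (-3.53825, -7.02258, 3.05875)),
        ("O4'", 'O', 2, (-2.03503, -5.70020, 2.43490)),
        ("C1'", 'C', 2, (-2.01430, -5.25184, 1.09591)),
        ("H1'", 'H', 2, (-2.88068, -4.65732, 0.80602)),
        ("C2'", 'C', 2, (-1.97306, -6.50738, 0.25174)),
        ("H2'", 'H', 2, (-0.95698, -6.89111, 0.15983)),
        ("H2''", 'H', 2, (-2.37668, -6.32937, -0.74501)),
        ("C3'", 'C', 2, (-2.85678, -7.46043, 1.04663)),
        ("H3'", 'H', 2, (-2.56421, -8.49774, 0.88383)),
        ("O3'", 'O', 2, (-4.22711, -7.30507, 0.69594)),
        ('N1', 'N', 2, (-0.87004, -4.40444, 0.92497)),
        ('C2', 'C', 2, (-1.01335, -3.03061, 0.63541)),
        ('N3', 'N', 2, (0.18704, -2.32671, 0.49432)),
        ('C4', 'C', 2, (1.47148, -2.83647, 0.60956)),
        ('C5', 'C', 2, (1.54160, -4.29039, 0.91448)),
        ('C6', 'C', 2, (0.39370, -4.96723, 1.05028)),
        ('O2', 'O', 2, (-2.10158, -2.46573, 0.51084)),
        ('O4', 'O', 2, (2.48629, -2.15866, 0.47412)),
        ('C7', 'C', 2, (2.89231, -4.91591, 1.05324)),
        ('H3', 'H', 2, (0.10839, -1.33566, 0.28606)),
        ('H71', 'H', 2, (3.44591, -4.80378, 0.12246)),
        ('H72', 'H', 2, (2.78611, -5.97528, 1.28487)),
        ('H73', 'H', 2, (3.44043, -4.43141, 1.86084)),
        ('H6', 'H', 2, (0.40029, -6.03008, 1.27342)),
    ],
}
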
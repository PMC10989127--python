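"""WGS-84 inverse-geodesic reference distances for fixed coordinate pairs.

Each row is (lat1, lon1, lat2, lon2, distance_m); distances were computed
once with an independent geodesic implementation.  The first pair is the
equatorial quarter arc, a * pi / 2.
"""

REFERENCE_PAIRS = [
    (0.0000, 0.0000, 0.0000, 90.0000, 10018754.171319),
    (78.2255, -65.6626, 54.1542, -111.9723, 3215169.646611),
    (-16.3607, 49.9227, -6.8954, -38.9327, 9682082.398444),
    (-61.4884, -73.3101, 47.9161, -80.9434, 12148303.566864),
    (-68.8402, 177.8199, -18.8891, -110.2934, 7334117.652488),
    (-41.0001, 145.3556, 41.5522, 1.5723, 17009613.890574),
    (46.7217, 174.9686, -10.1159, 94.4548, 10107605.987865),
    (-25.5900, -155.4988, 64.6748, 69.3335, 14624218.882687),
    (75.5300, 45.4799, -28.8744, 15.7714, 11772481.884650),
    (-53.4631, -3.4099, -66.7889, 56.9532, 3491834.103478),
    (-6.5434, 168.6267, 50.6063, -11.1952, 15119178.090530),
    (-52.5203, -49.3249, 63.7562, -6.5136, 13417586.551846),
    (-42.9637, 64.4377, 74.6394, -58.3312, 15508953.493070),
    (43.6499, -84.5883, 11.6910, -27.0196, 6526741.199640),
    (-64.5918, -112.5143, 35.2127, -76.2486, 11508899.210710),
    (-7.4484, -112.7187, 43.8494, 36.2266, 14975036.012869),
    (-66.4479, -43.2118, 20.4417, 121.9858, 14783207.852861),
    (9.7065, 124.2347, 35.6783, 43.2597, 8577123.708186),
    (-78.6073, -0.6887, -18.1070, -130.8305, 8839896.009771),
    (77.7179, 104.0296, -53.9535, 24.2446, 15560062.930651),
]
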
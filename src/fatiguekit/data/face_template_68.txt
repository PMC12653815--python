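# Canonical 68-point 3-D face template (synthetic generic anthropometric layout).
# Units: millimetres. Axes: x right, y down, z away from camera.
# Origin: midpoint between the eye lines. iBUG-68 point order, 0-based.
# Columns: x y z
-78.000 0.000 72.000
-76.501 21.460 69.716
-72.063 42.095 63.213
-64.855 61.113 53.481
-55.154 77.782 42.000
-43.334 91.462 30.519
-29.849 101.627 20.787
-15.217 107.886 14.284
-0.000 110.000 12.000
15.217 107.886 14.284
29.849 101.627 20.787
43.334 91.462 30.519
55.154 77.782 42.000
64.855 61.113 53.481
72.063 42.095 63.213
76.501 21.460 69.716
78.000 0.000 72.000
-62.000 -12.000 2.000
-52.000 -16.000 -2.000
-41.000 -18.000 -4.000
-30.000 -16.000 -3.000
-20.000 -13.000 -1.000
20.000 -13.000 -1.000
30.000 -16.000 -3.000
41.000 -18.000 -4.000
52.000 -16.000 -2.000
62.000 -12.000 2.000
0.000 -2.000 -6.000
0.000 12.000 -11.000
0.000 25.000 -15.000
0.000 36.000 -20.000
-14.000 44.000 -6.000
-7.000 46.000 -9.000
0.000 48.000 -11.000
7.000 46.000 -9.000
14.000 44.000 -6.000
-48.000 0.000 0.000
-40.000 -4.200 0.000
-26.000 -4.200 0.000
-18.000 0.000 0.000
-26.000 4.200 0.000
-40.000 4.200 0.000
18.000 0.000 0.000
26.000 -4.200 0.000
40.000 -4.200 0.000
48.000 0.000 0.000
40.000 4.200 0.000
26.000 4.200 0.000
-27.000 62.000 8.000
-18.000 56.000 8.000
-9.000 52.820 8.000
0.000 51.500 8.000
9.000 52.820 8.000
18.000 56.000 8.000
27.000 62.000 8.000
18.000 68.000 8.000
9.000 71.180 8.000
0.000 72.500 8.000
-9.000 71.180 8.000
-18.000 68.000 8.000
-20.000 62.000 8.000
-8.000 58.000 8.000
0.000 57.500 8.000
8.000 58.000 8.000
20.000 62.000 8.000
8.000 66.000 8.000
0.000 66.500 8.000
-8.000 66.000 8.000
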
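id,half_life_value,half_life_unit,emissions,daughters
H-3,12.32,y,,
C-11,20.36,min,511.0:99.75,
C-14,5700.0,y,,
N-13,9.97,min,511.0:99.8,
O-15,122.24,s,511.0:99.9,
F-18,109.77,min,511.0:96.75,
Na-22,2.602,y,1274.5:99.9,
Na-24,14.96,h,1368.6:100.0,
P-32,14.27,d,,
P-33,25.35,d,,
S-35,87.37,d,,
K-42,12.36,h,1524.6:18.1,
Ca-45,162.6,d,,
Ca-47,4.536,d,1297.1:67.0,
Sc-44,3.97,h,1157.0:99.9;511.0:94.4,
Sc-46,83.79,d,889.3:100.0;1120.5:99.9,
Sc-47,3.349,d,159.4:68.3,
Cr-51,27.7,d,320.1:9.9,
Mn-52,5.591,d,744.2:90.0;935.5:94.5;1434.1:100.0,
Mn-54,312.2,d,834.8:99.98,
Fe-52,8.28,h,168.7:99.2;511.0:56,Mn-52:1.0
Fe-59,44.49,d,1099.2:56.5;1291.6:43.2,
Co-55,17.53,h,931.1:75.0;477.2:20.2,
Co-57,271.74,d,122.1:85.6;136.5:10.7,
Co-58,70.86,d,810.8:99.5,
Co-60,5.271,y,1173.2:99.85;1332.5:99.98,
Cu-60,23.7,min,1332.5:88.0;511.0:92.6,
Cu-61,3.34,h,283.0:12.2;511.0:61.5,
Cu-62,9.67,min,511.0:97.5,
Cu-64,12.7,h,511.0:17.6;1345.8:0.5,
Cu-67,61.83,h,184.6:48.7;93.3:16.1,
Zn-62,9.19,h,596.6:26.0;548.4:15.3,Cu-62:1.0
Zn-65,243.9,d,1115.5:50.0,
Ga-66,9.49,h,1039.2:37.0;511.0:57,
Ga-67,3.2617,d,93.3:38.8;184.6:21.4;300.2:16.6,
Ga-68,67.71,min,511.0:88.9;1077.3:3.2,
Ge-68,270.95,d,,Ga-68:1.0
As-72,26.0,h,834.0:81.0;511.0:88,
As-74,17.77,d,595.8:59.0;511.0:29,
As-76,26.24,h,559.1:45.0,
Se-75,119.8,d,264.7:58.9;136.0:58.3,
Br-76,16.2,h,559.1:74.0;511.0:54.5,
Br-77,57.04,h,239.0:23.1;521.0:22.4,
Rb-81,4.572,h,190.5:64.9;511.0:27.1,
Rb-82,1.258,min,511.0:95.45;776.5:15.1,
Rb-86,18.64,d,1077.0:8.6,
Sr-82,25.35,d,,Rb-82:1.0
Sr-85,64.85,d,514.0:96.0,
Sr-89,50.56,d,,
Sr-90,28.79,y,,Y-90:1.0
Y-86,14.74,h,1076.6:82.5;511.0:31.8,
Y-88,106.63,d,898.0:93.7;1836.1:99.2,
Y-90,64.05,h,,
Zr-89,78.41,h,909.0:99.0;511.0:22.75,
Nb-95,34.99,d,765.8:99.8,
Mo-99,65.98,h,739.5:12.3;181.1:6.1,Tc-99m:0.886
Tc-99m,6.01,h,140.5:89.0,
Ru-97,2.83,d,215.7:85.6;324.5:10.8,
Ru-103,39.25,d,497.1:91.0,
Rh-105,35.36,h,319.1:19.1,
Pd-103,16.99,d,357.5:0.022,
Ag-111,7.45,d,342.1:6.7,
Cd-109,461.9,d,88.0:3.6,
In-110,4.92,h,657.8:97.7,
In-111,2.8047,d,171.3:90.7;245.4:94.1,
In-114m,49.51,d,190.3:15.6,
Sn-113,115.09,d,391.7:64.97,
Sn-117m,14.0,d,158.6:86.4,
Sb-124,60.2,d,602.7:97.8;1691.0:47.6,
I-123,13.22,h,159.0:83.3,
I-124,4.176,d,602.7:62.9;511.0:22.5,
I-125,59.4,d,35.5:6.7,
I-131,8.025,d,364.5:81.5;637.0:7.2,
Xe-127,36.34,d,202.9:68.3;172.1:25.4,
Xe-133,5.243,d,81.0:36.9,
Cs-131,9.69,d,29.5:21.1,
Cs-134,2.065,y,604.7:97.6;795.9:85.5,
Cs-137,30.08,y,661.7:85.1,
Ba-133,10.55,y,356.0:62.1;81.0:32.9,
La-140,1.679,d,1596.2:95.4;487.0:45.5,
Ce-139,137.64,d,165.9:79.9,
Ce-141,32.51,d,145.4:48.3,
Nd-147,10.98,d,91.1:28.1;531.0:13.4,
Pm-149,53.08,h,286.0:3.1,
Sm-153,46.28,h,103.2:29.2,
Eu-152,13.52,y,121.8:28.5;344.3:26.6;1408.0:21.0,
Gd-153,240.4,d,97.4:29.0;103.2:21.1,
Tb-149,4.12,h,165.0:26.4;352.2:29.4,
Tb-152,17.5,h,344.3:63.5;511.0:17,
Tb-155,5.32,d,86.5:32.0;105.3:25.1,
Tb-161,6.89,d,74.6:10.2;48.9:17.0,
Dy-165,2.334,h,94.7:3.8,
Dy-166,81.6,h,82.5:13.0,Ho-166:1.0
Ho-166,26.82,h,80.6:6.7,
Er-169,9.39,d,,
Tm-170,128.6,d,84.3:2.5,
Yb-169,32.02,d,63.1:43.6;197.9:35.9,
Yb-175,4.185,d,396.3:13.2,
Lu-177,6.647,d,208.4:10.4;113.0:6.2,
Re-186,3.718,d,137.2:9.5,
Re-188,17.0,h,155.0:15.6,
Os-191,15.4,d,129.4:26.5,
Ir-192,73.83,d,316.5:82.9;468.1:47.8,
Pt-195m,4.01,d,98.9:11.4,
Au-198,2.695,d,411.8:95.6,
Au-199,3.139,d,158.4:40.0,
Hg-197,64.14,h,77.4:18.7,
Tl-201,3.042,d,167.4:10.0;70.8:73.7,
Tl-208,3.053,min,2614.5:99.8;583.2:85.0,
Pb-203,51.92,h,279.2:80.9,
Pb-212,10.6,h,238.6:43.6,Bi-212:1.0
Bi-212,60.55,min,727.3:6.7,Po-212:0.6406;Tl-208:0.3594
Bi-213,45.61,min,440.0:25.9,Po-213:0.9791;Tl-209:0.0209
Po-212,0.299,s,,
Po-213,3.72,s,,Pb-209:1.0
Po-216,0.145,s,,Pb-212:1.0
Pb-209,3.234,h,,
Tl-209,2.162,min,1567.1:99.7,Pb-209:1.0
At-211,7.214,h,687.0:0.26,
At-217,0.0323,s,,Bi-213:1.0
Rn-220,55.6,s,,Po-216:1.0
Rn-222,3.8235,d,,
Fr-221,4.801,min,218.0:11.4,At-217:1.0
Ra-223,11.43,d,269.5:13.9;154.2:5.7,
Ra-224,3.63,d,241.0:4.1,Rn-220:1.0
Ra-226,1600.0,y,186.2:3.6,Rn-222:1.0
Ac-225,9.92,d,99.8:1.0,Fr-221:1.0
Ac-227,21.77,y,,Th-227:0.9862
Th-227,18.69,d,236.0:12.9,Ra-223:1.0
U-235,703800000.0,y,185.7:57.0,
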
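sample_id,sepal_length,sepal_width,petal_length,petal_width,species
iris_000,5.1,3.5,1.4,0.2,setosa
iris_001,4.9,3.0,1.4,0.2,setosa
iris_002,4.7,3.2,1.3,0.2,setosa
iris_003,4.6,3.1,1.5,0.2,setosa
iris_004,5.0,3.6,1.4,0.2,setosa
iris_005,5.4,3.9,1.7,0.4,setosa
iris_006,4.6,3.4,1.4,0.3,setosa
iris_007,5.0,3.4,1.5,0.2,setosa
iris_008,4.4,2.9,1.4,0.2,setosa
iris_009,4.9,3.1,1.5,0.1,setosa
iris_010,5.4,3.7,1.5,0.2,setosa
iris_011,4.8,3.4,1.6,0.2,setosa
iris_012,4.8,3.0,1.4,0.1,setosa
iris_013,4.3,3.0,1.1,0.1,setosa
iris_014,5.8,4.0,1.2,0.2,setosa
iris_015,5.7,4.4,1.5,0.4,setosa
iris_016,5.4,3.9,1.3,0.4,setosa
iris_017,5.1,3.5,1.4,0.3,setosa
iris_018,5.7,3.8,1.7,0.3,setosa
iris_019,5.1,3.8,1.5,0.3,setosa
iris_020,5.4,3.4,1.7,0.2,setosa
iris_021,5.1,3.7,1.5,0.4,setosa
iris_022,4.6,3.6,1.0,0.2,setosa
iris_023,5.1,3.3,1.7,0.5,setosa
iris_024,4.8,3.4,1.9,0.2,setosa
iris_025,5.0,3.0,1.6,0.2,setosa
iris_026,5.0,3.4,1.6,0.4,setosa
iris_027,5.2,3.5,1.5,0.2,setosa
iris_028,5.2,3.4,1.4,0.2,setosa
iris_029,4.7,3.2,1.6,0.2,setosa
iris_030,4.8,3.1,1.6,0.2,setosa
iris_031,5.4,3.4,1.5,0.4,setosa
iris_032,5.2,4.1,1.5,0.1,setosa
iris_033,5.5,4.2,1.4,0.2,setosa
iris_034,4.9,3.1,1.5,0.2,setosa
iris_035,5.0,3.2,1.2,0.2,setosa
iris_036,5.5,3.5,1.3,0.2,setosa
iris_037,4.9,3.6,1.4,0.1,setosa
iris_038,4.4,3.0,1.3,0.2,setosa
iris_039,5.1,3.4,1.5,0.2,setosa
iris_040,5.0,3.5,1.3,0.3,setosa
iris_041,4.5,2.3,1.3,0.3,setosa
iris_042,4.4,3.2,1.3,0.2,setosa
iris_043,5.0,3.5,1.6,0.6,setosa
iris_044,5.1,3.8,1.9,0.4,setosa
iris_045,4.8,3.0,1.4,0.3,setosa
iris_046,5.1,3.8,1.6,0.2,setosa
iris_047,4.6,3.2,1.4,0.2,setosa
iris_048,5.3,3.7,1.5,0.2,setosa
iris_049,5.0,3.3,1.4,0.2,setosa
iris_050,7.0,3.2,4.7,1.4,versicolor
iris_051,6.4,3.2,4.5,1.5,versicolor
iris_052,6.9,3.1,4.9,1.5,versicolor
iris_053,5.5,2.3,4.0,1.3,versicolor
iris_054,6.5,2.8,4.6,1.5,versicolor
iris_055,5.7,2.8,4.5,1.3,versicolor
iris_056,6.3,3.3,4.7,1.6,versicolor
iris_057,4.9,2.4,3.3,1.0,versicolor
iris_058,6.6,2.9,4.6,1.3,versicolor
iris_059,5.2,2.7,3.9,1.4,versicolor
iris_060,5.0,2.0,3.5,1.0,versicolor
iris_061,5.9,3.0,4.2,1.5,versicolor
iris_062,6.0,2.2,4.0,1.0,versicolor
iris_063,6.1,2.9,4.7,1.4,versicolor
iris_064,5.6,2.9,3.6,1.3,versicolor
iris_065,6.7,3.1,4.4,1.4,versicolor
iris_066,5.6,3.0,4.5,1.5,versicolor
iris_067,5.8,2.7,4.1,1.0,versicolor
iris_068,6.2,2.2,4.5,1.5,versicolor
iris_069,5.6,2.5,3.9,1.1,versicolor
iris_070,5.9,3.2,4.8,1.8,versicolor
iris_071,6.1,2.8,4.0,1.3,versicolor
iris_072,6.3,2.5,4.9,1.5,versicolor
iris_073,6.1,2.8,4.7,1.2,versicolor
iris_074,6.4,2.9,4.3,1.3,versicolor
iris_075,6.6,3.0,4.4,1.4,versicolor
iris_076,6.8,2.8,4.8,1.4,versicolor
iris_077,6.7,3.0,5.0,1.7,versicolor
iris_078,6.0,2.9,4.5,1.5,versicolor
iris_079,5.7,2.6,3.5,1.0,versicolor
iris_080,5.5,2.4,3.8,1.1,versicolor
iris_081,5.5,2.4,3.7,1.0,versicolor
iris_082,5.8,2.7,3.9,1.2,versicolor
iris_083,6.0,2.7,5.1,1.6,versicolor
iris_084,5.4,3.0,4.5,1.5,versicolor
iris_085,6.0,3.4,4.5,1.6,versicolor
iris_086,6.7,3.1,4.7,1.5,versicolor
iris_087,6.3,2.3,4.4,1.3,versicolor
iris_088,5.6,3.0,4.1,1.3,versicolor
iris_089,5.5,2.5,4.0,1.3,versicolor
iris_090,5.5,2.6,4.4,1.2,versicolor
iris_091,6.1,3.0,4.6,1.4,versicolor
iris_092,5.8,2.6,4.0,1.2,versicolor
iris_093,5.0,2.3,3.3,1.0,versicolor
iris_094,5.6,2.7,4.2,1.3,versicolor
iris_095,5.7,3.0,4.2,1.2,versicolor
iris_096,5.7,2.9,4.2,1.3,versicolor
iris_097,6.2,2.9,4.3,1.3,versicolor
iris_098,5.1,2.5,3.0,1.1,versicolor
iris_099,5.7,2.8,4.1,1.3,versicolor
iris_100,6.3,3.3,6.0,2.5,virginica
iris_101,5.8,2.7,5.1,1.9,virginica
iris_102,7.1,3.0,5.9,2.1,virginica
iris_103,6.3,2.9,5.6,1.8,virginica
iris_104,6.5,3.0,5.8,2.2,virginica
iris_105,7.6,3.0,6.6,2.1,virginica
iris_106,4.9,2.5,4.5,1.7,virginica
iris_107,7.3,2.9,6.3,1.8,virginica
iris_108,6.7,2.5,5.8,1.8,virginica
iris_109,7.2,3.6,6.1,2.5,virginica
iris_110,6.5,3.2,5.1,2.0,virginica
iris_111,6.4,2.7,5.3,1.9,virginica
iris_112,6.8,3.0,5.5,2.1,virginica
iris_113,5.7,2.5,5.0,2.0,virginica
iris_114,5.8,2.8,5.1,2.4,virginica
iris_115,6.4,3.2,5.3,2.3,virginica
iris_116,6.5,3.0,5.5,1.8,virginica
iris_117,7.7,3.8,6.7,2.2,virginica
iris_118,7.7,2.6,6.9,2.3,virginica
iris_119,6.0,2.2,5.0,1.5,virginica
iris_120,6.9,3.2,5.7,2.3,virginica
iris_121,5.6,2.8,4.9,2.0,virginica
iris_122,7.7,2.8,6.7,2.0,virginica
iris_123,6.3,2.7,4.9,1.8,virginica
iris_124,6.7,3.3,5.7,2.1,virginica
iris_125,7.2,3.2,6.0,1.8,virginica
iris_126,6.2,2.8,4.8,1.8,virginica
iris_127,6.1,3.0,4.9,1.8,virginica
iris_128,6.4,2.8,5.6,2.1,virginica
iris_129,7.2,3.0,5.8,1.6,virginica
iris_130,7.4,2.8,6.1,1.9,virginica
iris_131,7.9,3.8,6.4,2.0,virginica
iris_132,6.4,2.8,5.6,2.2,virginica
iris_133,6.3,2.8,5.1,1.5,virginica
iris_134,6.1,2.6,5.6,1.4,virginica
iris_135,7.7,3.0,6.1,2.3,virginica
iris_136,6.3,3.4,5.6,2.4,virginica
iris_137,6.4,3.1,5.5,1.8,virginica
iris_138,6.0,3.0,4.8,1.8,virginica
iris_139,6.9,3.1,5.4,2.1,virginica
iris_140,6.7,3.1,5.6,2.4,virginica
iris_141,6.9,3.1,5.1,2.3,virginica
iris_142,5.8,2.7,5.1,1.9,virginica
iris_143,6.8,3.2,5.9,2.3,virginica
iris_144,6.7,3.3,5.7,2.5,virginica
iris_145,6.7,3.0,5.2,2.3,virginica
iris_146,6.3,2.5,5.0,1.9,virginica
iris_147,6.5,3.0,5.2,2.0,virginica
iris_148,6.2,3.4,5.4,2.3,virginica
iris_149,5.9,3.0,5.1,1.8,virginica
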
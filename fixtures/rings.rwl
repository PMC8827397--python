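C001    1986   225   220   209   308
C001    1990   188   227   183   198    98   176   153   131   135   230
C001    2000   217   204   191   206   222   195   172   181   158   173
C001    2010   287   177   123   185   197   234   314   999
C002    1986   228   281   255   398
C002    1990   375   584   386   247   110   193   257   226   252   245
C002    2000   270   291   221   284   283   204   250   330   246   278
C002    2010   248   202   200   269   290   275   330   999
C003    1986   184   157   164   202
C003    1990   159   340   237   170   114   122   174   126   143   212
C003    2000   177   222   144   188   162   140   161   187   139   225
C003    2010   269   206   190   186   271   278   373   999
C004    1986   220   276   253   341
C004    1990   194   402   379   271    69   138   106   114   149   135
C004    2000   236   283   183   217   234   119   133   181   174   269
C004    2010   279   208   171   308   282   293   609   999
C005    1986    93    88    77   148
C005    1990   102   171    93   168    31    53    36    43    50    95
C005    2000    98    99    74    94    45    42    66   111    63   123
C005    2010   144    60    18   123   123   177   389   999
C006    1986   122   128   122   175
C006    1990   171   167   189   184   105   102   150   157   106   192
C006    2000   140   152   125   150   172   121    98   129   107   125
C006    2010   128   128   162   142   172   145   233   999
C007    1986   162   209   174   283
C007    1990   157   181   133   132    44    65   109   106   100   120
C007    2000   112   127   112   134   153   119    80   112   110   185
C007    2010   115   157   140   188   177   142   155   999
C008    1986   124   157   158   210
C008    1990   174   249   222   137    74   132   163    85   112   135
C008    2000   128   169   146   143    99    89   105   157   107   107
C008    2010   138   106   164   254   174   202   414   999
C009    1986    85   100    69    72
C009    1990    60    70    74    85     0    25    39    58    72    80
C009    2000    56    56    72    59    56    70    59    44    44    74
C009    2010    63    71    71    70    72    76   101   999
C010    1986    75   128   114   203
C010    1990   126   181   191   126    41    65    69    59    80    95
C010    2000   113   128   117   133    99    91    93   118    71   136
C010    2010   142   145   103   118   115   168   221   999
C011    1986   131   128   101   229
C011    1990   134   246   178   128    43    84    66    48    85   160
C011    2000   136   148    93   139   109   110   106   118   108   116
C011    2010   135    90    78   119   167   165   328   999
C012    1986   118    90    97   142
C012    1990   135   140   102   105    49    48    54    82    59   106
C012    2000   141   125    52   103   104    89    55   110    70   126
C012    2010   118   148    72    85   141   129   136   999
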